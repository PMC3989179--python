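"""Sequence simulator with known species structure and planted introgression.

Datasets are generated under the two-parameter (transition-biased) Markov
substitution process that underlies the K2P distance, so divergence targets
have a closed-form calibration: with the rate matrix scaled to one expected
substitution per site per unit time, the expected K2P distance between two
sequences equals the total branch length separating them.

Species sit on a star tree by default.  A root sequence is drawn from the
base frequencies; each species ancestor evolves for (inter - intra)/2 and each
individual for intra/2 from its species ancestor, so that expected pairwise
divergence is ``intra`` within species and ``inter`` between them.  Shared
haplotypes and unbalanced sampling arise naturally.  Introgression directives
give selected individuals the mtDNA of a donor species (their sequence
evolves from the donor ancestor) while their morphology label — and any
nuclear locus — stays with the true species, the pattern left by maternally
inherited mtDNA crossing a species boundary.

Every dataset ships with a ground-truth table (true species, morphology
label, mtDNA origin, haplotype), so each pipeline stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .alignment_io import Alignment, SpecimenRecord, collapse_haplotypes

__all__ = [
    "SimulationError",
    "IntrogressionEvent",
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_reference_suite",
]

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class IntrogressionEvent:
    """Fraction of a recipient species' individuals carrying donor mtDNA.

    Species are 1-based indices into ``SimConfig.sample_sizes``.  The realized
    count is round(fraction * n_recipient), exactly.
    """

    donor: int
    recipient: int
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise SimulationError("introgression fraction must be in [0, 1]")
        if self.donor == self.recipient:
            raise SimulationError("donor and recipient must differ")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults emulate a COI-like barcode: 650 sites, mean intraspecific
    divergence 0.01 and interspecific scale 0.15 substitutions/site
    (divergence scales in the range reported for well-sampled mollusc
    barcoding surveys), transition/transversion rate ratio kappa = 4.
    A 16S-like fragment would use ``length=440``.
    """

    sample_sizes: tuple[int, ...] = (6, 6, 6, 6, 6)
    length: int = 650
    intra: float = 0.01
    inter: float = 0.15
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    introgression: tuple[IntrogressionEvent, ...] = ()
    locus: str = "mtCOI"

    def __post_init__(self) -> None:
        if not self.sample_sizes or any(n < 1 for n in self.sample_sizes):
            raise SimulationError("every species needs at least one individual")
        if self.length < 1:
            raise SimulationError("length must be positive")
        if self.intra < 0 or self.inter < 0:
            raise SimulationError("divergence targets must be non-negative")
        if self.n_species > 1 and self.intra >= self.inter:
            raise SimulationError(
                "intraspecific target must be below the interspecific target"
            )
        if self.kappa <= 0:
            raise SimulationError("kappa must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or any(
            f <= 0 for f in self.base_freqs
        ):
            raise SimulationError("base_freqs must be positive and sum to 1")
        for ev in self.introgression:
            for sp in (ev.donor, ev.recipient):
                if not (1 <= sp <= self.n_species):
                    raise SimulationError(f"introgression references species {sp}")
        # a target that cannot place even one expected substitution on the
        # alignment is unrealisable
        for name, target in (("intra", self.intra), ("inter", self.inter)):
            relevant = name == "intra" or self.n_species > 1
            if relevant and 0.0 < target and target * self.length < 1.0:
                raise SimulationError(
                    f"{name} target {target} incompatible with length "
                    f"{self.length}: expected substitutions < 1 site"
                )

    @property
    def n_species(self) -> int:
        return len(self.sample_sizes)


def _rate_matrix(kappa: float) -> np.ndarray:
    """K2P rate matrix scaled to one expected substitution/site/unit time.

    Transitions (A<->G, C<->T) at rate alpha = kappa*beta, each transversion
    at beta, alpha + 2*beta = 1.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    q = np.full((4, 4), beta)
    for a, b in ((0, 2), (1, 3)):  # A<->G, C<->T
        q[a, b] = q[b, a] = alpha
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _evolve(
    rng: np.random.Generator, seq: np.ndarray, t: float, kappa: float
) -> np.ndarray:
    """Evolve an encoded (0..3) sequence for branch length t."""
    if t == 0.0:
        return seq.copy()
    p = expm(_rate_matrix(kappa) * t)
    pcum = np.cumsum(p, axis=1)
    u = rng.random(seq.size)
    return (u[:, None] > pcum[seq]).sum(axis=1).astype(np.int64)


@dataclass
class SimulatedDataset:
    """Alignment, ground truth and the configuration that produced them."""

    alignment: Alignment
    truth: pd.DataFrame
    config: SimConfig


def simulate_dataset(cfg: SimConfig, seed: int | np.random.Generator) -> SimulatedDataset:
    """Generate one dataset under the configured conditions.

    Reproducible: the same config and seed yield byte-identical sequences.
    The truth table has one row per specimen with columns ``specimen_id``,
    ``species`` (true species), ``morphology_label`` (always the true
    species), ``mt_origin`` (differs for introgressed individuals) and
    ``haplotype``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K, L = cfg.n_species, cfg.length
    root = rng.choice(4, size=L, p=np.asarray(cfg.base_freqs))
    t_species = (cfg.inter - cfg.intra) / 2.0 if K > 1 else 0.0
    ancestors = [_evolve(rng, root, t_species, cfg.kappa) for _ in range(K)]

    # which individuals carry foreign mtDNA (exact rounded counts per directive)
    mt_origin: dict[tuple[int, int], int] = {}
    for ev in cfg.introgression:
        n_rec = cfg.sample_sizes[ev.recipient - 1]
        n_intro = round(ev.fraction * n_rec)
        picks = rng.choice(n_rec, size=n_intro, replace=False)
        for j in picks:
            mt_origin[(ev.recipient, int(j))] = ev.donor

    records: list[SpecimenRecord] = []
    sequences: list[str] = []
    truth_rows = []
    for sp in range(1, K + 1):
        name = f"sp{sp}"
        for j in range(cfg.sample_sizes[sp - 1]):
            origin = mt_origin.get((sp, j), sp)
            seq = _evolve(rng, ancestors[origin - 1], cfg.intra / 2.0, cfg.kappa)
            sid = f"{name}_{j:02d}"
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    morphospecies_label=name,
                    locality=f"site{sp}",
                    in_britain_or_ireland=True,
                    source="new",
                    locus=cfg.locus,
                )
            )
            sequences.append("".join(_BASES[seq]))
            truth_rows.append(
                {
                    "specimen_id": sid,
                    "species": name,
                    "morphology_label": name,
                    "mt_origin": f"sp{origin}",
                }
            )
    aln = Alignment(records, sequences)
    haps = collapse_haplotypes(aln)
    hap_of = {sid: hid for hid, m in zip(haps.ids, haps.members) for sid in m}
    truth = pd.DataFrame(truth_rows)
    truth["haplotype"] = truth["specimen_id"].map(hap_of)
    return SimulatedDataset(alignment=aln, truth=truth, config=cfg)


def _relabel_to(
    ds: SimulatedDataset, template: SimulatedDataset, locus: str
) -> SimulatedDataset:
    """Give a dataset the specimen ids and species labels of a template
    (used to pair a nuclear locus with a mitochondrial one)."""
    if len(ds.alignment) != len(template.alignment):
        raise SimulationError("paired datasets must have equal specimen counts")
    new_records = [
        replace(rec, specimen_id=t.specimen_id, morphospecies_label=t.morphospecies_label, locality=t.locality, locus=locus)
        for rec, t in zip(ds.alignment.records, template.alignment.records)
    ]
    aln = Alignment(new_records, list(ds.alignment.sequences))
    haps = collapse_haplotypes(aln)
    hap_of = {sid: hid for hid, m in zip(haps.ids, haps.members) for sid in m}
    truth = template.truth.copy()
    truth["mt_origin"] = truth["species"]  # nuclear locus follows the species
    truth["haplotype"] = truth["specimen_id"].map(hap_of)
    return SimulatedDataset(alignment=aln, truth=truth, config=ds.config)


def simulate_reference_suite(
    seed: int,
) -> dict[str, SimulatedDataset | dict[str, SimulatedDataset]]:
    """A fixed battery of datasets exercising every pipeline stage.

    clean_k2 / clean_k5 / clean_k9
        K well-separated species (intra 0.01, inter 0.15, six individuals
        each, 650 sites) — delimitation should recover K.
    degenerate
        One species with near-zero variation (intra 0.002): too little
        variation for gap-based delimitation; the sweep must flag it.
    unbalanced
        Two species sampled 1 vs 50 — the rarity regime in which
        distance-based delimitation is still expected to hold.
    introgression
        Two species with one-way introgression (half of species 2's
        individuals carry species 1 mtDNA), the maternal-capture pattern.
    shared_pool
        Paired loci: a mitochondrial dataset of six distinct species and a
        nuclear dataset in which five of them share one undifferentiated
        gene pool while the sixth stays distinct.
    """
    children = np.random.SeedSequence(seed).spawn(7)
    rngs = [np.random.default_rng(c) for c in children]
    suite: dict[str, SimulatedDataset | dict[str, SimulatedDataset]] = {}
    for rng, (name, k) in zip(rngs[:3], [("clean_k2", 2), ("clean_k5", 5), ("clean_k9", 9)]):
        suite[name] = simulate_dataset(SimConfig(sample_sizes=(6,) * k), rng)
    suite["degenerate"] = simulate_dataset(
        SimConfig(sample_sizes=(8,), intra=0.002, inter=0.0), rngs[3]
    )
    suite["unbalanced"] = simulate_dataset(
        SimConfig(sample_sizes=(1, 50)), rngs[4]
    )
    suite["introgression"] = simulate_dataset(
        SimConfig(
            sample_sizes=(8, 8),
            intra=0.005,
            inter=0.10,
            introgression=(IntrogressionEvent(donor=1, recipient=2, fraction=0.5),),
        ),
        rngs[5],
    )
    mito = simulate_dataset(SimConfig(sample_sizes=(6,) * 6, intra=0.005), rngs[6])
    nuclear_raw = simulate_dataset(
        SimConfig(sample_sizes=(30, 6), intra=0.01, inter=0.10, locus="nuclearITS1"),
        rngs[6],
    )
    suite["shared_pool"] = {
        "mito": mito,
        "nuclear": _relabel_to(nuclear_raw, mito, locus="nuclearITS1"),
    }
    return suite
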