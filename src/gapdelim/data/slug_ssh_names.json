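{
  "comment": "Checklist names matched by each refined SSH species (empty list: no known name, i.e. a species additional to the fauna). SSH 11 absorbed two checklist names; SSHs 7 and 8 share one. The two degenerate monotypic-family species (too little sequence variation to delimit) are appended outside the refinement engine.",
  "name_map": {
    "1A": ["Arion ater"],
    "1B+1C": [],
    "2": ["Arion rufus"],
    "3": [],
    "4": ["Arion vulgaris"],
    "5": ["Arion flagellus"],
    "6": ["Arion fuscus"],
    "7": ["Arion subfuscus"],
    "8": ["Arion subfuscus"],
    "9+10": [],
    "11": ["Arion circumscriptus", "Arion silvaticus"],
    "12": ["Arion fasciatus"],
    "13": ["Arion distinctus"],
    "14": ["Arion hortensis"],
    "15": ["Arion intermedius"],
    "16": ["Arion occultus"],
    "17": ["Arion owenii"],
    "18": [],
    "19": ["Geomalacus maculosus"],
    "20": ["Limax cinereoniger"],
    "21": ["Limax maximus"],
    "22": [],
    "23": ["Limacus flavus"],
    "24": ["Limacus maculatus"],
    "25": ["Lehmannia marginata"],
    "26": ["Ambigolimax valentianus"],
    "27": ["Ambigolimax nyctelius"],
    "28": ["Malacolimax tenellus"],
    "29": ["Deroceras agreste"],
    "30": ["Deroceras reticulatum"],
    "31": ["Deroceras invadens"],
    "32": [],
    "33+34+35+36": ["Deroceras laeve"],
    "37": ["Milax gagates"],
    "38": ["Tandonia budapestensis"],
    "39": [],
    "40": ["Tandonia sowerbyi"],
    "41": ["Tandonia rustica"],
    "42": ["Testacella haliotidea"],
    "43": ["Testacella maugei"],
    "44": ["Testacella scutulum"],
    "45": [],
    "46": ["Boettgerilla pallens"],
    "47": ["Selenochlamys ysbryda"]
  },
  "degenerate_family_species": [
    {"ssh_id": "46", "applied_name": "Boettgerilla pallens"},
    {"ssh_id": "47", "applied_name": "Selenochlamys ysbryda"}
  ]
}
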