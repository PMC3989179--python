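# The 36 slug species recorded as established in Britain and Ireland
# prior to the delimitation survey (one name per line).
Arion ater
Arion rufus
Arion vulgaris
Arion flagellus
Arion fuscus
Arion subfuscus
Arion circumscriptus
Arion silvaticus
Arion fasciatus
Arion distinctus
Arion hortensis
Arion intermedius
Arion occultus
Arion owenii
Geomalacus maculosus
Limax cinereoniger
Limax maximus
Limacus flavus
Limacus maculatus
Lehmannia marginata
Ambigolimax valentianus
Ambigolimax nyctelius
Malacolimax tenellus
Deroceras agreste
Deroceras reticulatum
Deroceras invadens
Deroceras laeve
Milax gagates
Tandonia budapestensis
Tandonia sowerbyi
Tandonia rustica
Testacella haliotidea
Testacella maugei
Testacella scutulum
Boettgerilla pallens
Selenochlamys ysbryda
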