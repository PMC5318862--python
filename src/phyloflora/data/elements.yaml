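# Geographical-distribution element vocabularies.
#
# Base codes partition the coded taxa at each rank; super-groups are unions
# of base codes (COSM belongs to neither the tropical nor the temperate
# super-group). ESHD is an inert legacy code retained for round-tripping
# older tables; it belongs to no super-group and no analysis references it.
#
# The family-level set below is a documented placeholder: family-level
# element typologies are flora-specific, so override this section with your
# own vocabulary file when analysing real data.
genus:
  codes:
    COSM: Cosmopolitan
    PT: Pantropic
    TATAD: Tropical Asia and tropical America disjunct
    OWT: Old World tropic
    TATA: Tropical Asia to tropical Australia
    TATAF: Tropical Asia to tropical Africa
    TA: Tropical Asia
    NT: North temperate
    EANAD: East Asia and North America disjunct
    OWTE: Old World temperate
    TEA: Temperate Asia
    MWACA: Mediterranean, west Asia to central Asia
    CA: Central Asia
    EA: East Asia
    EC: Endemic to China
    ESHD: Unresolved legacy code (inert)
  inert: [ESHD]
  supergroups:
    ALL TRO: [PT, TATAD, OWT, TATA, TATAF, TA]
    ALL TEM: [NT, EANAD, OWTE, TEA, MWACA, CA, EA, EC]
family:
  codes:
    COSM: Cosmopolitan
    PT: Pantropic
    TATAD: Tropical Asia and tropical America disjunct
    OWT: Old World tropic
    TATA: Tropical Asia to tropical Australia
    TATAF: Tropical Asia to tropical Africa
    TA: Tropical Asia
    NT: North temperate
    EANAD: East Asia and North America disjunct
    OWTE: Old World temperate
    TEA: Temperate Asia
    EA: East Asia
    EC: Endemic to China
  supergroups:
    ALL TRO: [PT, TATAD, OWT, TATA, TATAF, TA]
    ALL TEM: [NT, EANAD, OWTE, TEA, EA, EC]
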