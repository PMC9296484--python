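{
  "groups": [
    {
      "name": "Feeding habit",
      "max_code": 5,
      "traits": [
        {"name": "Absorber", "abbr": "FH1"},
        {"name": "Deposit feeder", "abbr": "FH2"},
        {"name": "Shredder", "abbr": "FH3"},
        {"name": "Scraper", "abbr": "FH4"},
        {"name": "Filter-feeder", "abbr": "FH5"},
        {"name": "Piercer (plants or animals)", "abbr": "FH6"},
        {"name": "Predator (carver/engulfer/swallower)", "abbr": "FH7"},
        {"name": "Parasite", "abbr": "FH8"}
      ]
    },
    {
      "name": "Locomotion and substrate relation",
      "max_code": 5,
      "traits": [
        {"name": "Flier", "abbr": "LS1"},
        {"name": "Surface swimmer", "abbr": "LS2"},
        {"name": "Full water swimmer", "abbr": "LS3"},
        {"name": "Crawler", "abbr": "LS4"},
        {"name": "Burrower (epibenthic)", "abbr": "LS5"},
        {"name": "Interstitial (endobenthic)", "abbr": "LS6"},
        {"name": "Temporarily attached", "abbr": "LS7"},
        {"name": "Permanently attached", "abbr": "LS8"}
      ]
    },
    {
      "name": "Food type",
      "max_code": 5,
      "traits": [
        {"name": "Fine sediment + microorganisms", "abbr": "FT1"},
        {"name": "Fine detritus (<= 1 mm)", "abbr": "FT2"},
        {"name": "Dead plant (> 1 mm)", "abbr": "FT3"},
        {"name": "Living microphytes", "abbr": "FT4"},
        {"name": "Living macrophytes", "abbr": "FT5"},
        {"name": "Dead animal (> 1 mm)", "abbr": "FT6"},
        {"name": "Living microinvertebrates", "abbr": "FT7"},
        {"name": "Living macroinvertebrates", "abbr": "FT8"},
        {"name": "Vertebrates", "abbr": "FT9"}
      ]
    },
    {
      "name": "Respiration",
      "max_code": 5,
      "traits": [
        {"name": "Tegument (respiration through the body surface)", "abbr": "RS1"},
        {"name": "Gill (respiration using special respiration organs)", "abbr": "RS2"},
        {"name": "Plastron (respiration using a thin layer of air around the body)", "abbr": "RS3"},
        {"name": "Spiracle (aerial) (respiration using small openings on the body surface)", "abbr": "RS4"},
        {"name": "Hydrostatic vesicle (aerial) (respiration using air within a small blister)", "abbr": "RS5"}
      ]
    },
    {
      "name": "Maximal potential size",
      "max_code": 5,
      "traits": [
        {"name": "<= 0.25 cm", "abbr": "MS1"},
        {"name": "> 0.25-0.5 cm", "abbr": "MS2"},
        {"name": "> 0.5-1 cm", "abbr": "MS3"},
        {"name": "> 1-2 cm", "abbr": "MS4"},
        {"name": "> 2-4 cm", "abbr": "MS5"},
        {"name": "> 4-8 cm", "abbr": "MS6"},
        {"name": "> 8 cm", "abbr": "MS7"}
      ]
    },
    {
      "name": "Resistance form",
      "max_code": 5,
      "traits": [
        {"name": "Eggs, gemmula, statoblasts", "abbr": "RF1"},
        {"name": "Cocoon", "abbr": "RF2"},
        {"name": "Housing against desiccation", "abbr": "RF3"},
        {"name": "Diapause or dormancy", "abbr": "RF4"},
        {"name": "None", "abbr": "RF5"}
      ]
    },
    {
      "name": "Dispersal",
      "max_code": 3,
      "traits": [
        {"name": "Aquatic passive", "abbr": "DI1"},
        {"name": "Aquatic active", "abbr": "DI2"},
        {"name": "Aerial passive", "abbr": "DI3"},
        {"name": "Aerial active", "abbr": "DI4"}
      ]
    },
    {
      "name": "Aquatic stage",
      "max_code": 3,
      "traits": [
        {"name": "Egg", "abbr": "AS1"},
        {"name": "Larva", "abbr": "AS2"},
        {"name": "Nymph", "abbr": "AS3"},
        {"name": "Adult", "abbr": "AS4"}
      ]
    },
    {
      "name": "Life cycle duration period",
      "max_code": 3,
      "traits": [
        {"name": "<= 1 year", "abbr": "LC1"},
        {"name": "> 1 year", "abbr": "LC2"}
      ]
    },
    {
      "name": "Potential number of cycles per year",
      "max_code": 3,
      "traits": [
        {"name": "< 1, semivoltine", "abbr": "PN1"},
        {"name": "1 monovoltine", "abbr": "PN2"},
        {"name": "> 1 polyvoltine", "abbr": "PN3"}
      ]
    },
    {
      "name": "Reproduction",
      "max_code": 5,
      "traits": [
        {"name": "Ovoviviparity", "abbr": "RP1"},
        {"name": "Isolated eggs, free", "abbr": "RP2"},
        {"name": "Isolated eggs, cemented", "abbr": "RP3"},
        {"name": "Clutches, cemented or fixed", "abbr": "RP4"},
        {"name": "Clutches, free", "abbr": "RP5"},
        {"name": "Clutches, in vegetation", "abbr": "RP6"},
        {"name": "Clutches, terrestrial", "abbr": "RP7"},
        {"name": "Asexual reproduction", "abbr": "RP8"}
      ]
    }
  ]
}
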