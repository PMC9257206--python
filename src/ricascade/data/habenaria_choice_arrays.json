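{
  "description": "Reference dataset for three sympatric nocturnal-moth-pollinated Habenaria orchids (Lijiang, Yunnan): choice-array floral-transition counts per pollinator, flowering-overlap proportions, and the published per-barrier RI values for every directed species pair.",
  "species": {
    "lim": "Habenaria limprichtii",
    "dav": "Habenaria davidii",
    "del": "Habenaria delavayi"
  },
  "arrays": {
    "lim_dav": {
      "species": ["lim", "dav"],
      "pollinators": {
        "Deilephila elpenor": {
          "interspecific_bouts": 2, "total_bouts": 7,
          "n_aa": 2, "n_bb": 14, "n_ab": 3, "n_ba": 1,
          "published_CI_mean": 0.70, "published_CI_sd": 0.69
        },
        "Trichoplusia intermixta": {
          "interspecific_bouts": 0, "total_bouts": 4,
          "n_aa": 14, "n_bb": 0, "n_ab": 0, "n_ba": 0,
          "published_CI_mean": 1.00, "published_CI_sd": 0.00
        }
      },
      "total": {"n_aa": 16, "n_bb": 14, "n_ab": 3, "n_ba": 1},
      "n_bouts": 11, "n_visits": 34
    },
    "lim_del": {
      "species": ["lim", "del"],
      "pollinators": {
        "Deilephila elpenor": {
          "interspecific_bouts": 0, "total_bouts": 3,
          "n_aa": 8, "n_bb": 0, "n_ab": 0, "n_ba": 0,
          "published_CI_mean": 1.00, "published_CI_sd": 0.00
        },
        "Trichoplusia intermixta": {
          "interspecific_bouts": 2, "total_bouts": 6,
          "n_aa": 2, "n_bb": 13, "n_ab": 2, "n_ba": 2,
          "published_CI_mean": 0.86, "published_CI_sd": 0.20
        }
      },
      "total": {"n_aa": 10, "n_bb": 13, "n_ab": 2, "n_ba": 2},
      "n_bouts": 9, "n_visits": 27
    }
  },
  "flowering_overlap_S": {"lim_dav": 0.7377, "del_lim": 0.3833, "del_dav": 0.3026},
  "published_ladders": {
    "lim x dav": {"phenology": 0.026, "ethological": 0.882, "ovary": -0.006, "fruit": -0.004, "seed": 0.044},
    "dav x lim": {"phenology": 0.011, "ethological": 0.647, "ovary": 0.029, "fruit": 0.002, "seed": -0.013},
    "lim x del": {"phenology": 0.605, "ethological": 0.667, "ovary": 0.798, "fruit": 1.0, "seed": 1.0},
    "del x lim": {"phenology": 0.559, "ethological": 0.733, "ovary": 0.5, "fruit": 1.0, "seed": 1.0},
    "dav x del": {"phenology": 0.667, "ethological": null, "ovary": 0.913, "fruit": 1.0, "seed": 1.0},
    "del x dav": {"phenology": 0.558, "ethological": null, "ovary": 0.45, "fruit": 1.0, "seed": 1.0}
  },
  "published_totals": {
    "lim x dav": 0.895, "dav x lim": 0.660,
    "lim x del": 1.0, "del x lim": 1.0,
    "dav x del": 1.0, "del x dav": 1.0
  },
  "notes": "Barrier labels follow the life-cycle order phenology, ethological, style, ovary, fruit, seed; only a single pollinia-pistil value (pollen tubes reaching the ovary) was published per direction, stored under 'ovary'. The ethological barrier is null for the dav/del pair, which shares no pollinator. Published per-pollinator CI means/SDs are stored for reference; the individual bout sequences behind the 0.70 +/- 0.69 and 0.86 +/- 0.20 rows were not published and cannot be reconstructed from the transition cells."
}
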