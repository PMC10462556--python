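{
  "schema": "llrsim-stats/1",
  "comment": "Per-category module duration and occurrence summaries from the 13-video LLR study cohort. Durations in seconds, 'mean (sd)'; occurrence statistics are unconditional (surgeries without the module count as 0 occurrences); duration statistics are over occurrences in surgeries where the module occurred. Insufflation (P07M02) duration was not recognizable on video and is carried as 0. The S78/S5GB packaging row is typographically ambiguous in the source table; the resolution used here (S78 63(20) occ 1(0); S5GB 138(3) occ 1.3(0.6)) is editable data, not code.",
  "min_resection_s": {"S56": 476.0, "S78": 540.0, "S5GB": 922.0},
  "prep_time_s": 3600.0,
  "categories": {
    "S56": {
      "idle": {"duration_mean_s": 193.0, "duration_sd_s": 67.0},
      "modules": {
        "P05M02": {"duration_mean_s": 252.0, "duration_sd_s": 188.0, "occ_mean": 2.0, "occ_sd": 1.2},
        "P06M01": {"duration_mean_s": 85.0, "duration_sd_s": 47.0, "occ_mean": 5.0, "occ_sd": 1.2},
        "P07M01": {"duration_mean_s": 157.0, "duration_sd_s": 87.0, "occ_mean": 3.6, "occ_sd": 0.5},
        "P07M02": {"duration_mean_s": 0.0, "duration_sd_s": 0.0, "occ_mean": 1.0, "occ_sd": 0.0},
        "P08aM01": {"duration_mean_s": 90.0, "duration_sd_s": 0.0, "occ_mean": 0.2, "occ_sd": 0.4},
        "P08aM02": {"duration_mean_s": 548.0, "duration_sd_s": 43.0, "occ_mean": 0.6, "occ_sd": 0.9},
        "P08aM03": {"duration_mean_s": 400.0, "duration_sd_s": 370.0, "occ_mean": 5.6, "occ_sd": 8.8},
        "P08aM05": {"duration_mean_s": 134.0, "duration_sd_s": 120.0, "occ_mean": 1.6, "occ_sd": 2.0},
        "P08aM06": {"duration_mean_s": 410.0, "duration_sd_s": 387.0, "occ_mean": 5.4, "occ_sd": 8.4},
        "P10M01": {"duration_mean_s": 176.0, "duration_sd_s": 86.0, "occ_mean": 1.0, "occ_sd": 0.0},
        "P10M02": {"duration_mean_s": 1343.0, "duration_sd_s": 951.0, "occ_mean": 2.6, "occ_sd": 1.8},
        "P11M02": {"duration_mean_s": 222.0, "duration_sd_s": 172.0, "occ_mean": 6.4, "occ_sd": 3.3},
        "P13M02": {"duration_mean_s": 101.0, "duration_sd_s": 81.0, "occ_mean": 1.0, "occ_sd": 0.0},
        "P13M03": {"duration_mean_s": 52.0, "duration_sd_s": 47.0, "occ_mean": 1.0, "occ_sd": 0.5},
        "P13M04": {"duration_mean_s": 223.0, "duration_sd_s": 220.0, "occ_mean": 3.4, "occ_sd": 1.7},
        "P13M05": {"duration_mean_s": 100.0, "duration_sd_s": 17.0, "occ_mean": 1.0, "occ_sd": 1.4},
        "P13M06": {"duration_mean_s": 252.0, "duration_sd_s": 120.0, "occ_mean": 3.0, "occ_sd": 1.2},
        "P13M07": {"duration_mean_s": 0.0, "duration_sd_s": 0.0, "occ_mean": 0.0, "occ_sd": 0.0}
      }
    },
    "S78": {
      "idle": {"duration_mean_s": 931.0, "duration_sd_s": 1154.0},
      "modules": {
        "P05M02": {"duration_mean_s": 1259.0, "duration_sd_s": 1491.0, "occ_mean": 3.4, "occ_sd": 1.3},
        "P06M01": {"duration_mean_s": 181.0, "duration_sd_s": 146.0, "occ_mean": 7.8, "occ_sd": 2.9},
        "P07M01": {"duration_mean_s": 132.0, "duration_sd_s": 73.0, "occ_mean": 4.0, "occ_sd": 0.7},
        "P07M02": {"duration_mean_s": 0.0, "duration_sd_s": 0.0, "occ_mean": 1.0, "occ_sd": 0.0},
        "P08aM01": {"duration_mean_s": 2692.0, "duration_sd_s": 0.0, "occ_mean": 0.6, "occ_sd": 1.3},
        "P08aM02": {"duration_mean_s": 191.0, "duration_sd_s": 10.0, "occ_mean": 0.4, "occ_sd": 0.5},
        "P08aM03": {"duration_mean_s": 0.0, "duration_sd_s": 0.0, "occ_mean": 0.0, "occ_sd": 0.0},
        "P08aM05": {"duration_mean_s": 0.0, "duration_sd_s": 0.0, "occ_mean": 0.0, "occ_sd": 0.0},
        "P08aM06": {"duration_mean_s": 0.0, "duration_sd_s": 0.0, "occ_mean": 0.0, "occ_sd": 0.0},
        "P10M01": {"duration_mean_s": 197.0, "duration_sd_s": 85.0, "occ_mean": 1.2, "occ_sd": 0.4},
        "P10M02": {"duration_mean_s": 1421.0, "duration_sd_s": 736.0, "occ_mean": 1.6, "occ_sd": 0.9},
        "P11M02": {"duration_mean_s": 291.0, "duration_sd_s": 190.0, "occ_mean": 7.0, "occ_sd": 4.4},
        "P13M02": {"duration_mean_s": 63.0, "duration_sd_s": 20.0, "occ_mean": 1.0, "occ_sd": 0.0},
        "P13M03": {"duration_mean_s": 105.0, "duration_sd_s": 32.0, "occ_mean": 1.4, "occ_sd": 0.9},
        "P13M04": {"duration_mean_s": 225.0, "duration_sd_s": 222.0, "occ_mean": 4.8, "occ_sd": 3.3},
        "P13M05": {"duration_mean_s": 99.0, "duration_sd_s": 75.0, "occ_mean": 1.2, "occ_sd": 1.6},
        "P13M06": {"duration_mean_s": 218.0, "duration_sd_s": 144.0, "occ_mean": 2.4, "occ_sd": 2.9},
        "P13M07": {"duration_mean_s": 98.0, "duration_sd_s": 9.0, "occ_mean": 0.8, "occ_sd": 0.8}
      }
    },
    "S5GB": {
      "idle": {"duration_mean_s": 322.0, "duration_sd_s": 51.0},
      "modules": {
        "P05M02": {"duration_mean_s": 235.0, "duration_sd_s": 184.0, "occ_mean": 1.0, "occ_sd": 1.0},
        "P06M01": {"duration_mean_s": 222.0, "duration_sd_s": 146.0, "occ_mean": 6.0, "occ_sd": 1.7},
        "P07M01": {"duration_mean_s": 170.0, "duration_sd_s": 40.0, "occ_mean": 4.0, "occ_sd": 0.0},
        "P07M02": {"duration_mean_s": 0.0, "duration_sd_s": 0.0, "occ_mean": 1.0, "occ_sd": 0.0},
        "P08aM01": {"duration_mean_s": 209.0, "duration_sd_s": 0.0, "occ_mean": 0.7, "occ_sd": 1.1},
        "P08aM02": {"duration_mean_s": 855.0, "duration_sd_s": 414.0, "occ_mean": 4.0, "occ_sd": 1.7},
        "P08aM03": {"duration_mean_s": 150.0, "duration_sd_s": 111.0, "occ_mean": 1.33, "occ_sd": 0.6},
        "P08aM05": {"duration_mean_s": 60.0, "duration_sd_s": 26.0, "occ_mean": 1.67, "occ_sd": 0.6},
        "P08aM06": {"duration_mean_s": 38.0, "duration_sd_s": 10.0, "occ_mean": 1.67, "occ_sd": 0.6},
        "P10M01": {"duration_mean_s": 259.0, "duration_sd_s": 93.0, "occ_mean": 1.0, "occ_sd": 0.0},
        "P10M02": {"duration_mean_s": 1210.0, "duration_sd_s": 253.0, "occ_mean": 1.7, "occ_sd": 0.6},
        "P11M02": {"duration_mean_s": 347.0, "duration_sd_s": 291.0, "occ_mean": 8.0, "occ_sd": 7.0},
        "P13M02": {"duration_mean_s": 138.0, "duration_sd_s": 3.0, "occ_mean": 1.3, "occ_sd": 0.6},
        "P13M03": {"duration_mean_s": 227.0, "duration_sd_s": 205.0, "occ_mean": 1.3, "occ_sd": 0.6},
        "P13M04": {"duration_mean_s": 128.0, "duration_sd_s": 72.0, "occ_mean": 2.7, "occ_sd": 0.6},
        "P13M05": {"duration_mean_s": 75.0, "duration_sd_s": 70.0, "occ_mean": 0.7, "occ_sd": 0.6},
        "P13M06": {"duration_mean_s": 438.0, "duration_sd_s": 340.0, "occ_mean": 1.7, "occ_sd": 0.6},
        "P13M07": {"duration_mean_s": 0.0, "duration_sd_s": 0.0, "occ_mean": 0.0, "occ_sd": 0.0}
      }
    }
  }
}
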