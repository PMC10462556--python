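{
  "schema": "llrsim-workflow/1",
  "category": "S5GB",
  "comment": "Workflow for wedge resection of liver segment 5 with gallbladder removal (cholecystectomy). The cystic-duct handling chain (mobilize gallbladder, isolate, permanently occlude with clips, divide) is mandatory and ordered. Mobilization of the gallbladder may resume later (second row without a printed percentage); its occurrence probability is 1.0 by consistency with the mandatory chain.",
  "sections": [
    {
      "phase": "07",
      "name": "Operative field access",
      "free_order": false,
      "entries": [
        {"label": "Trocar 1", "module": "P07M01", "probability": 1.0},
        {"label": "Insufflation", "module": "P07M02", "probability": 1.0},
        {"label": "Trocar 2", "module": "P07M01", "probability": 1.0},
        {"label": "Trocar 3", "module": "P07M01", "probability": 1.0},
        {"label": "Trocar 4", "module": "P07M01", "probability": 1.0}
      ]
    },
    {
      "phase": "08a",
      "name": "Destructive Isolation",
      "free_order": false,
      "entries": [
        {"label": "Fat/Adhesion", "module": "P08aM01", "probability": 0.33},
        {"label": "Mobilization gallbladder", "module": "P08aM02", "probability": 1.0},
        {"label": "Isolation", "module": "P08aM03", "probability": 1.0},
        {"label": "Perm. Occlusion", "module": "P08aM05", "probability": 1.0},
        {"label": "Division", "module": "P08aM06", "probability": 1.0},
        {"label": "Mobilization gallbladder (resumed)", "module": "P08aM02", "probability": null}
      ]
    },
    {
      "phase": "10",
      "name": "Treatment",
      "free_order": false,
      "entries": [
        {"label": "Marking", "module": "P10M01", "probability": 1.0},
        {"label": "Resection", "module": "P10M02", "probability": 1.0}
      ]
    },
    {
      "phase": "13",
      "name": "Wrap-up",
      "free_order": true,
      "entries": [
        {"label": "Leakage clean-up", "module": "P13M04", "probability": 1.0},
        {"label": "Leak Testing", "module": "P13M05", "probability": 0.66},
        {"label": "Leak Closure", "module": "P13M06", "probability": 1.0},
        {"label": "Package", "module": "P13M02", "probability": 1.0},
        {"label": "Removal", "module": "P13M03", "probability": 1.0}
      ]
    },
    {
      "phase": "13",
      "name": "Wrap-up (untimed)",
      "free_order": false,
      "entries": [
        {"label": "Desufflation", "module": "P13M08", "probability": 1.0},
        {"label": "Incision closing", "module": "P13M09", "probability": 1.0}
      ]
    }
  ],
  "insert_anytime": [
    {"label": "Imaging", "module": "P05M02", "probability": 1.0},
    {"label": "Planning", "module": "P06M01", "probability": 1.0},
    {"label": "Leakage clean-up (complication)", "module": "P11M02", "probability": 1.0}
  ],
  "untimed_modules": ["P13M08", "P13M09"],
  "questions": [
    {"id": "fat_adhesion_dissection", "kind": "static", "after": "Insufflation",
     "outcomes": {"yes": 0.33, "no": 0.67}},
    {"id": "leak_testing", "kind": "static", "after": "Leakage clean-up",
     "outcomes": {"yes": 0.66, "no": 0.34}}
  ],
  "precedence": [
    ["P07M01", "P10M01"],
    ["P08aM02", "P08aM03"],
    ["P08aM03", "P08aM05"],
    ["P08aM05", "P08aM06"],
    ["P08aM03", "P08aM06"],
    ["P10M01", "P10M02"],
    ["P10M02", "P13M02"]
  ],
  "most_probable_path": [
    "Trocar 1", "Insufflation", "Imaging", "Planning",
    "Trocar 2", "Trocar 3", "Trocar 4",
    "Mobilization gallbladder", "Isolation", "Perm. Occlusion", "Division",
    "Marking", "Resection",
    "Leakage clean-up (complication)",
    "Leakage clean-up", "Leak Testing", "Leak Closure", "Package", "Removal",
    "Desufflation", "Incision closing"
  ]
}
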