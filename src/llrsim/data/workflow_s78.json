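{
  "schema": "llrsim-workflow/1",
  "category": "S78",
  "comment": "Workflow for wedge resection of posterosuperior liver segments 7 & 8. No supply-duct isolation, occlusion or division was observed in this category (tumors located in the upper parts of the segments), so the graph contains no P08aM03/P08aM05/P08aM06 nodes.",
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
        {"label": "Trocar 4", "module": "P07M01", "probability": 0.8},
        {"label": "Trocar 5", "module": "P07M01", "probability": 0.2}
      ]
    },
    {
      "phase": "08a",
      "name": "Destructive Isolation",
      "free_order": false,
      "entries": [
        {"label": "Fat/Adhesion", "module": "P08aM01", "probability": 0.2},
        {"label": "Mobilization Liver", "module": "P08aM02", "probability": 0.4}
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
        {"label": "Leak Testing", "module": "P13M05", "probability": 0.6},
        {"label": "Leak Closure", "module": "P13M06", "probability": 0.6},
        {"label": "Irrigation", "module": "P13M07", "probability": 0.6},
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
    {"id": "place_trocar_4", "kind": "static", "after": "Trocar 3",
     "outcomes": {"yes": 0.8, "no": 0.2}},
    {"id": "place_trocar_5", "kind": "static", "after": "Trocar 4",
     "outcomes": {"yes": 0.2, "no": 0.8}},
    {"id": "fat_adhesion_dissection", "kind": "static", "after": "Insufflation",
     "outcomes": {"yes": 0.2, "no": 0.8}},
    {"id": "mobilize_liver", "kind": "static", "after": "Fat/Adhesion",
     "outcomes": {"yes": 0.4, "no": 0.6}},
    {"id": "leak_testing", "kind": "static", "after": "Leakage clean-up",
     "outcomes": {"yes": 0.6, "no": 0.4}}
  ],
  "precedence": [
    ["P07M01", "P10M01"],
    ["P10M01", "P10M02"],
    ["P10M02", "P13M02"]
  ],
  "most_probable_path": [
    "Trocar 1", "Insufflation", "Imaging", "Planning",
    "Trocar 2", "Trocar 3", "Trocar 4",
    "Marking", "Resection",
    "Leakage clean-up (complication)",
    "Leakage clean-up", "Leak Testing", "Leak Closure", "Irrigation",
    "Package", "Removal",
    "Desufflation", "Incision closing"
  ]
}
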