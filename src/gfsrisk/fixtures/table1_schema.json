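[
 {"name": "age", "kind": "numerical"},
 {"name": "sex", "kind": "categorical", "domain": ["male", "female"]},
 {"name": "smoking", "kind": "categorical", "domain": ["yes", "no"]},
 {"name": "heart_events_recently", "kind": "categorical", "domain": ["yes", "no"]}
]
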