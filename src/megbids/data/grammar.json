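{
    "entity_order": ["sub", "ses", "task", "acq", "run", "proc"],
    "run_pad_width": 2,
    "label_pattern": "[A-Za-z0-9]+",
    "suffixes": {
        "meg": {
            "required": ["sub", "task"],
            "optional": ["ses", "acq", "run", "proc"],
            "extensions": ["ds", "fif", "con", "sqd", "raw", "json"],
            "directory_extensions": ["ds"],
            "raw_extensions": ["ds", "fif", "con", "sqd", "raw"],
            "inheritable_extensions": ["json"],
            "placement": "modality-folder",
            "modality": "meg"
        },
        "channels": {
            "required": ["sub", "task"],
            "optional": ["ses", "acq", "run", "proc"],
            "extensions": ["tsv"],
            "inheritable_extensions": ["tsv"],
            "placement": "modality-folder",
            "modality": "meg"
        },
        "events": {
            "required": ["sub", "task"],
            "optional": ["ses", "acq", "run", "proc"],
            "extensions": ["tsv"],
            "inheritable_extensions": ["tsv"],
            "placement": "modality-folder",
            "modality": "meg"
        },
        "coordsystem": {
            "required": ["sub"],
            "optional": ["ses", "acq"],
            "extensions": ["json"],
            "placement": "session"
        },
        "headshape": {
            "required": ["sub"],
            "optional": ["ses", "acq"],
            "extensions": "*",
            "placement": "session"
        },
        "photo": {
            "required": ["sub"],
            "optional": ["ses", "acq"],
            "extensions": ["jpg"],
            "placement": "session"
        },
        "scans": {
            "required": ["sub"],
            "optional": ["ses"],
            "extensions": ["tsv"],
            "placement": "session"
        },
        "participants": {
            "required": [],
            "optional": [],
            "extensions": ["tsv"],
            "placement": "root",
            "bare": true
        },
        "dataset_description": {
            "required": [],
            "optional": [],
            "extensions": ["json"],
            "placement": "root",
            "bare": true
        },
        "T1w": {
            "required": ["sub"],
            "optional": ["ses", "acq", "run", "proc"],
            "extensions": ["json", "nii"],
            "placement": "modality-folder",
            "modality": "anat"
        }
    }
}
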