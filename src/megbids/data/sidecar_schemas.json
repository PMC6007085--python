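{
    "meg": {
        "kind": "json",
        "required": {
            "TaskName": {"type": "string"},
            "SamplingFrequency": {"type": "number", "exclusive_min": 0},
            "PowerLineFrequency": {"type": "number", "enum": [50, 60]},
            "DewarPosition": {"type": "string"},
            "SoftwareFilters": {"type": "object_or_na"},
            "DigitizedLandmarks": {"type": "boolean"},
            "DigitizedHeadPoints": {"type": "boolean"}
        },
        "optional": {
            "Manufacturer": {"type": "string"},
            "ManufacturersModelName": {"type": "string"},
            "RecordingDuration": {"type": "number", "min": 0},
            "RecordingType": {"type": "string", "enum": ["continuous", "epoched"]},
            "MEGChannelCount": {"type": "integer", "min": 0},
            "MEGREFChannelCount": {"type": "integer", "min": 0},
            "EEGChannelCount": {"type": "integer", "min": 0},
            "EOGChannelCount": {"type": "integer", "min": 0},
            "ECGChannelCount": {"type": "integer", "min": 0},
            "EMGChannelCount": {"type": "integer", "min": 0},
            "MiscChannelCount": {"type": "integer", "min": 0},
            "TriggerChannelCount": {"type": "integer", "min": 0},
            "AssociatedEmptyRoom": {"type": "string"}
        },
        "key_order": [
            "TaskName", "Manufacturer", "ManufacturersModelName",
            "SamplingFrequency", "PowerLineFrequency", "DewarPosition",
            "SoftwareFilters", "DigitizedLandmarks", "DigitizedHeadPoints",
            "RecordingDuration", "RecordingType",
            "MEGChannelCount", "MEGREFChannelCount", "EEGChannelCount",
            "EOGChannelCount", "ECGChannelCount", "EMGChannelCount",
            "MiscChannelCount", "TriggerChannelCount", "AssociatedEmptyRoom"
        ]
    },
    "coordsystem": {
        "kind": "json",
        "required": {
            "MEGCoordinateSystem": {"type": "string", "enum": ["CTF", "ElektaNeuromag", "KIT", "Other"]},
            "MEGCoordinateUnits": {"type": "string", "enum": ["m", "cm", "mm"]}
        },
        "optional": {
            "MEGCoordinateSystemDescription": {"type": "string"},
            "HeadCoilCoordinates": {"type": "vector_map"},
            "AnatomicalLandmarkCoordinates": {"type": "vector_map", "keys": ["NAS", "LPA", "RPA"]},
            "AnatomicalLandmarkCoordinateSystem": {"type": "string"},
            "AnatomicalLandmarkCoordinateUnits": {"type": "string", "enum": ["m", "cm", "mm"]}
        },
        "key_order": [
            "MEGCoordinateSystem", "MEGCoordinateUnits", "MEGCoordinateSystemDescription",
            "HeadCoilCoordinates", "AnatomicalLandmarkCoordinates",
            "AnatomicalLandmarkCoordinateSystem", "AnatomicalLandmarkCoordinateUnits"
        ]
    },
    "dataset_description": {
        "kind": "json",
        "required": {
            "Name": {"type": "string"},
            "BIDSVersion": {"type": "string"}
        },
        "optional": {
            "Authors": {"type": "array"},
            "License": {"type": "string"},
            "Acknowledgements": {"type": "string"},
            "HowToAcknowledge": {"type": "string"},
            "Funding": {"type": "array"},
            "ReferencesAndLinks": {"type": "array"},
            "DatasetDOI": {"type": "string"}
        },
        "key_order": ["Name", "BIDSVersion", "Authors", "License"]
    },
    "T1w": {
        "kind": "json",
        "required": {},
        "optional": {
            "AnatomicalLandmarkCoordinates": {"type": "vector_map", "keys": ["NAS", "LPA", "RPA"], "exact_keys": true},
            "CoordinateUnits": {"type": "string", "enum": ["m", "cm", "mm", "voxel"]}
        },
        "key_order": ["AnatomicalLandmarkCoordinates", "CoordinateUnits"]
    },
    "channels": {
        "kind": "tsv",
        "columns": {
            "name": {"required": true, "unique": true},
            "type": {"required": true, "enum": [
                "MEGMAG", "MEGGRADAXIAL", "MEGGRADPLANAR",
                "MEGREFMAG", "MEGREFGRADAXIAL",
                "EEG", "EOG", "ECG", "EMG", "TRIG", "MISC"
            ]},
            "units": {"required": true},
            "low_cutoff": {"type": "number_or_na"},
            "high_cutoff": {"type": "number_or_na"},
            "status": {"enum": ["good", "bad"]},
            "status_description": {}
        },
        "column_order": ["name", "type", "units", "low_cutoff", "high_cutoff", "status", "status_description"]
    },
    "events": {
        "kind": "tsv",
        "columns": {
            "onset": {"required": true, "type": "number", "min": 0},
            "duration": {"required": true, "type": "number_or_na", "min": 0},
            "trial_type": {},
            "value": {},
            "sample": {"type": "integer", "min": 0}
        },
        "column_order": ["onset", "duration", "trial_type", "value", "sample"]
    },
    "scans": {
        "kind": "tsv",
        "columns": {
            "filename": {"required": true, "unique": true},
            "acq_time": {"type": "datetime_or_na"}
        },
        "column_order": ["filename", "acq_time"]
    },
    "participants": {
        "kind": "tsv",
        "columns": {
            "participant_id": {"required": true, "unique": true, "pattern": "sub-[A-Za-z0-9]+"}
        },
        "column_order": ["participant_id"],
        "extra_columns": true
    }
}
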