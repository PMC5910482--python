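{
  "METABOLOMICS WORKBENCH": {
    "required": ["VERSION", "CREATED_ON"],
    "optional": ["STUDY_ID", "ANALYSIS_ID"],
    "value_rules": {
      "STUDY_ID": {"pattern": "^ST\\d+$"},
      "ANALYSIS_ID": {"pattern": "^AN\\d+$"}
    }
  },
  "PROJECT": {
    "required": [
      "PROJECT_TITLE", "PROJECT_SUMMARY", "INSTITUTE", "LAST_NAME",
      "FIRST_NAME", "ADDRESS", "EMAIL", "PHONE"
    ],
    "optional": [
      "PROJECT_TYPE", "DEPARTMENT", "LABORATORY", "FUNDING_SOURCE",
      "PROJECT_COMMENTS", "PUBLICATIONS", "CONTRIBUTIONS", "DOI"
    ],
    "value_rules": {
      "EMAIL": {"pattern": "^[^@\\s]+@[^@\\s]+\\.[^@\\s]+$"},
      "PHONE": {"pattern": "^[0-9+()\\-. ]{7,}$"}
    }
  },
  "STUDY": {
    "required": [
      "STUDY_TITLE", "INSTITUTE", "LAST_NAME", "FIRST_NAME", "ADDRESS",
      "EMAIL", "PHONE"
    ],
    "optional": [
      "STUDY_TYPE", "STUDY_SUMMARY", "DEPARTMENT", "LABORATORY",
      "SUBMIT_DATE", "NUM_GROUPS", "TOTAL_SUBJECTS", "STUDY_COMMENTS",
      "PUBLICATIONS"
    ],
    "value_rules": {
      "EMAIL": {"pattern": "^[^@\\s]+@[^@\\s]+\\.[^@\\s]+$"},
      "PHONE": {"pattern": "^[0-9+()\\-. ]{7,}$"}
    }
  },
  "SUBJECT": {
    "required": ["SUBJECT_TYPE", "SUBJECT_SPECIES"],
    "optional": [
      "TAXONOMY_ID", "GENOTYPE_STRAIN", "AGE_OR_AGE_RANGE", "WEIGHT_OR_WEIGHT_RANGE",
      "HEIGHT_OR_HEIGHT_RANGE", "GENDER", "HUMAN_RACE", "HUMAN_ETHNICITY",
      "SPECIES_GROUP", "CELL_STRAIN_DETAILS", "ANIMAL_ANIMAL_SUPPLIER",
      "SUBJECT_COMMENTS"
    ],
    "value_rules": {}
  },
  "SUBJECT_SAMPLE_FACTORS": {
    "required": [],
    "optional": [],
    "value_rules": {},
    "structural_rules": {"records": "ssf"}
  },
  "COLLECTION": {
    "required": ["COLLECTION_SUMMARY"],
    "optional": [
      "COLLECTION_PROTOCOL_ID", "COLLECTION_PROTOCOL_FILENAME",
      "COLLECTION_PROTOCOL_COMMENTS", "SAMPLE_TYPE", "COLLECTION_METHOD",
      "COLLECTION_LOCATION", "COLLECTION_FREQUENCY", "COLLECTION_DURATION",
      "COLLECTION_TIME", "VOLUMEORAMOUNT_COLLECTED", "STORAGE_CONDITIONS",
      "COLLECTION_VIALS", "STORAGE_VIALS", "COLLECTION_TUBE_TEMP"
    ],
    "value_rules": {}
  },
  "TREATMENT": {
    "required": ["TREATMENT_SUMMARY"],
    "optional": [
      "TREATMENT_PROTOCOL_ID", "TREATMENT_PROTOCOL_FILENAME",
      "TREATMENT_PROTOCOL_COMMENTS", "TREATMENT", "TREATMENT_COMPOUND",
      "TREATMENT_ROUTE", "TREATMENT_DOSE", "TREATMENT_DOSEVOLUME",
      "TREATMENT_DOSEDURATION", "TREATMENT_VEHICLE", "ANIMAL_VET_TREATMENTS",
      "ANIMAL_ANESTHESIA", "ANIMAL_FASTING", "ANIMAL_ENDP_EUTHANASIA",
      "HUMAN_FASTING", "CELL_ENVIR_COND", "CELL_HARVESTING"
    ],
    "value_rules": {}
  },
  "SAMPLEPREP": {
    "required": ["SAMPLEPREP_SUMMARY"],
    "optional": [
      "SAMPLEPREP_PROTOCOL_ID", "SAMPLEPREP_PROTOCOL_FILENAME",
      "SAMPLEPREP_PROTOCOL_COMMENTS", "PROCESSING_METHOD",
      "PROCESSING_STORAGE_CONDITIONS", "EXTRACTION_METHOD",
      "EXTRACT_CONCENTRATION_DILUTION", "EXTRACT_ENRICHMENT",
      "EXTRACT_CLEANUP", "EXTRACT_STORAGE", "SAMPLE_RESUSPENSION",
      "SAMPLE_DERIVATIZATION", "SAMPLE_SPIKING"
    ],
    "value_rules": {}
  },
  "CHROMATOGRAPHY": {
    "required": ["CHROMATOGRAPHY_TYPE", "INSTRUMENT_NAME", "COLUMN_NAME"],
    "optional": [
      "CHROMATOGRAPHY_SUMMARY", "METHODS_FILENAME", "METHODS_ID",
      "COLUMN_TEMPERATURE", "FLOW_GRADIENT", "FLOW_RATE", "INJECTION_TEMPERATURE",
      "INTERNAL_STANDARD", "RETENTION_INDEX", "RETENTION_TIME",
      "SAMPLE_INJECTION", "SOLVENT_A", "SOLVENT_B", "ANALYTICAL_TIME",
      "WEAK_WASH_SOLVENT_NAME", "STRONG_WASH_SOLVENT_NAME"
    ],
    "value_rules": {}
  },
  "ANALYSIS": {
    "required": ["ANALYSIS_TYPE"],
    "optional": [
      "LABORATORY_NAME", "OPERATOR_NAME", "DETECTOR_TYPE", "SOFTWARE_VERSION",
      "ACQUISITION_DATE", "ANALYSIS_PROTOCOL_FILE", "ACQUISITION_PARAMETERS_FILE",
      "PROCESSING_PARAMETERS_FILE", "DATA_FORMAT", "ANALYSIS_COMMENTS"
    ],
    "value_rules": {
      "ANALYSIS_TYPE": {"enum": ["MS", "NMR"]}
    }
  },
  "MS": {
    "required": ["INSTRUMENT_NAME", "INSTRUMENT_TYPE", "MS_TYPE", "ION_MODE"],
    "optional": [
      "MS_COMMENTS", "CAPILLARY_TEMPERATURE", "CAPILLARY_VOLTAGE",
      "COLLISION_ENERGY", "COLLISION_GAS", "DRY_GAS_FLOW", "DRY_GAS_TEMP",
      "FRAGMENT_VOLTAGE", "FRAGMENTATION_METHOD", "GAS_PRESSURE",
      "HELIUM_FLOW", "ION_SOURCE_TEMPERATURE", "ION_SPRAY_VOLTAGE",
      "IONIZATION", "IONIZATION_ENERGY", "IONIZATION_POTENTIAL",
      "MASS_ACCURACY", "PRECURSOR_TYPE", "REAGENT_GAS", "RESOLUTION_SETTING",
      "SCAN_RANGE_MOVERZ", "SCANNING", "SCANNING_CYCLE", "SCANNING_RANGE",
      "SKIMMER_VOLTAGE", "TUBE_LENS_VOLTAGE", "MS_RESULTS_FILE"
    ],
    "value_rules": {
      "ION_MODE": {"enum": ["POSITIVE", "NEGATIVE", "UNSPECIFIED", "MIXED"]}
    }
  },
  "NMR": {
    "required": [
      "INSTRUMENT_NAME", "INSTRUMENT_TYPE", "NMR_EXPERIMENT_TYPE",
      "SPECTROMETER_FREQUENCY"
    ],
    "optional": [
      "NMR_COMMENTS", "FIELD_FREQUENCY_LOCK", "STANDARD_CONCENTRATION",
      "NMR_PROBE", "NMR_SOLVENT", "NMR_TUBE_SIZE", "SHIMMING_METHOD",
      "PULSE_SEQUENCE", "WATER_SUPPRESSION", "PULSE_WIDTH", "POWER_LEVEL",
      "RECEIVER_GAIN", "OFFSET_FREQUENCY", "CHEMICAL_SHIFT_REF_CPD",
      "TEMPERATURE", "NUMBER_OF_SCANS", "DUMMY_SCANS", "ACQUISITION_TIME",
      "RELAXATION_DELAY", "SPECTRAL_WIDTH", "NUM_DATA_POINTS_ACQUIRED",
      "REAL_DATA_POINTS", "LINE_BROADENING", "ZERO_FILLING", "APODIZATION",
      "BASELINE_CORRECTION_METHOD", "CHEMICAL_SHIFT_REF_STD", "BINNED_INCREMENT",
      "BINNED_DATA_NORMALIZATION_METHOD", "BINNED_DATA_PROTOCOL_FILE",
      "BINNED_DATA_CHEMICAL_SHIFT_RANGE", "BINNED_DATA_EXCLUDED_RANGE"
    ],
    "value_rules": {}
  },
  "MS_METABOLITE_DATA": {
    "required": [],
    "optional": ["UNITS", "MS_METABOLITE_DATA_RESULTS_FILE"],
    "value_rules": {},
    "structural_rules": {"table": "results", "units_required": true}
  },
  "NMR_BINNED_DATA": {
    "required": [],
    "optional": ["UNITS", "NMR_BINNED_DATA_RESULTS_FILE"],
    "value_rules": {},
    "structural_rules": {"table": "results", "units_required": true}
  },
  "METABOLITES": {
    "required": [],
    "optional": [],
    "value_rules": {},
    "structural_rules": {"table": "annotation"}
  },
  "EXTENDED_MS_METABOLITE_DATA": {
    "required": [],
    "optional": [],
    "value_rules": {},
    "structural_rules": {"table": "extended"}
  }
}
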