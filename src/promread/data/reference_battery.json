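{
  "description": "Published per-questionnaire minimum reading ages (years) for 21 commonly used youth quality-of-life self-report questionnaires, by readability formula and section stream, with target age ranges and age-group classification. Formula ids: CLI Coleman-Liau, DC Power-updated Dale-Chall, FK Flesch-Kincaid, FOG Gunning Fog, FCST FORCAST; 'mean' is the printed cross-formula mean.",
  "questionnaires": [
    {
      "name": "AQOL-6D Adolescent Instrument",
      "target_age_min": 12, "target_age_max": 18, "n_items": 20, "age_group": "adolescent",
      "instructions": {"CLI": 16.8, "DC": 12.2, "FK": 15.8, "FOG": 18.9, "FCST": 15.6, "mean": 15.9},
      "items": {"CLI": 11.8, "DC": 10.8, "FK": 10.4, "FOG": 12.7, "FCST": 14.9, "mean": 12.1}
    },
    {
      "name": "CHU-9D",
      "target_age_min": 7, "target_age_max": 17, "n_items": 9, "age_group": "child_and_adolescent",
      "instructions": {"CLI": 8.6, "DC": 9.1, "FK": 8.3, "FOG": 8.9, "FCST": 14.6, "mean": 9.9},
      "items": {"CLI": 8.8, "DC": 10.6, "FK": 8.4, "FOG": 8.4, "FCST": 15.2, "mean": 10.3}
    },
    {
      "name": "EQ-5D-Y",
      "target_age_min": 8, "target_age_max": 15, "n_items": 6, "age_group": "child_and_adolescent",
      "instructions": {"CLI": 9.5, "DC": 10.5, "FK": 7.5, "FOG": 10.4, "FCST": 12.1, "mean": 10.0},
      "items": {"CLI": 11.4, "DC": 10.9, "FK": 10.9, "FOG": 12.5, "FCST": 16.5, "mean": 12.4}
    },
    {
      "name": "KIDSCREEN-52",
      "target_age_min": 8, "target_age_max": 18, "n_items": 52, "age_group": "child_and_adolescent",
      "instructions": {"CLI": 10.3, "DC": 9.4, "FK": 8.1, "FOG": 11.2, "FCST": 12.9, "mean": 10.4},
      "items": {"CLI": 10.4, "DC": 9.8, "FK": 7.7, "FOG": 9.5, "FCST": 13.3, "mean": 10.1}
    },
    {
      "name": "KIDSCREEN-27",
      "target_age_min": 8, "target_age_max": 18, "n_items": 27, "age_group": "child_and_adolescent",
      "instructions": {"CLI": 10.3, "DC": 9.4, "FK": 8.1, "FOG": 11.2, "FCST": 12.9, "mean": 10.4},
      "items": {"CLI": 10.2, "DC": 10.1, "FK": 8.1, "FOG": 10.1, "FCST": 13.2, "mean": 10.3}
    },
    {
      "name": "KIDSCREEN-10",
      "target_age_min": 8, "target_age_max": 18, "n_items": 10, "age_group": "child_and_adolescent",
      "instructions": {"CLI": 10.3, "DC": 9.4, "FK": 8.1, "FOG": 11.2, "FCST": 12.9, "mean": 10.4},
      "items": {"CLI": 12.3, "DC": 9.2, "FK": 6.4, "FOG": 11.2, "FCST": 12.9, "mean": 10.4}
    },
    {
      "name": "Kid-KINDL",
      "target_age_min": 7, "target_age_max": 13, "n_items": 24, "age_group": "child",
      "instructions": {"CLI": 10.7, "DC": 9.5, "FK": 7.8, "FOG": 9.9, "FCST": 13.4, "mean": 10.3},
      "items": {"CLI": 7.2, "DC": 10.1, "FK": 6.6, "FOG": 8.7, "FCST": 13.1, "mean": 9.1}
    },
    {
      "name": "Kiddo-KINDL",
      "target_age_min": 14, "target_age_max": 17, "n_items": 24, "age_group": "adolescent",
      "instructions": {"CLI": 10.7, "DC": 9.5, "FK": 7.8, "FOG": 9.8, "FCST": 13.3, "mean": 10.2},
      "items": {"CLI": 7.0, "DC": 10.1, "FK": 6.8, "FOG": 9.0, "FCST": 13.0, "mean": 9.2}
    },
    {
      "name": "PedsQL 4.0 Generic Core Scales - Child",
      "target_age_min": 8, "target_age_max": 12, "n_items": 23, "age_group": "child",
      "instructions": {"CLI": 7.6, "DC": 11.4, "FK": 8.5, "FOG": 10.0, "FCST": 13.3, "mean": 10.2},
      "items": {"CLI": 7.0, "DC": 9.6, "FK": 7.0, "FOG": 9.1, "FCST": 13.1, "mean": 9.2}
    },
    {
      "name": "PedsQL 4.0 SF15 Generic Core Scales - Child",
      "target_age_min": 8, "target_age_max": 12, "n_items": 15, "age_group": "child",
      "instructions": {"CLI": 7.6, "DC": 10.6, "FK": 8.5, "FOG": 10.0, "FCST": 13.3, "mean": 10.0},
      "items": {"CLI": 7.2, "DC": 9.9, "FK": 7.1, "FOG": 9.0, "FCST": 13.3, "mean": 9.3}
    },
    {
      "name": "PedsQL 4.0 Generic Core Scales - Teen",
      "target_age_min": 13, "target_age_max": 18, "n_items": 23, "age_group": "adolescent",
      "instructions": {"CLI": 7.6, "DC": 10.6, "FK": 8.5, "FOG": 10.0, "FCST": 13.3, "mean": 10.0},
      "items": {"CLI": 7.0, "DC": 9.9, "FK": 7.0, "FOG": 9.1, "FCST": 13.1, "mean": 9.2}
    },
    {
      "name": "PedsQL 4.0 SF15 Generic Core Scales - Teen",
      "target_age_min": 13, "target_age_max": 18, "n_items": 15, "age_group": "adolescent",
      "instructions": {"CLI": 7.6, "DC": 10.6, "FK": 8.5, "FOG": 10.0, "FCST": 13.3, "mean": 10.0},
      "items": {"CLI": 7.3, "DC": 10.1, "FK": 7.1, "FOG": 9.0, "FCST": 13.3, "mean": 9.4}
    },
    {
      "name": "PQ-LES-Q",
      "target_age_min": 6, "target_age_max": 17, "n_items": 15, "age_group": "child_and_adolescent",
      "instructions": null,
      "items": {"CLI": 10.8, "DC": 9.6, "FK": 7.6, "FOG": 9.3, "FCST": 14.9, "mean": 10.4}
    },
    {
      "name": "PROMIS Global Health 7",
      "target_age_min": 8, "target_age_max": 17, "n_items": 7, "age_group": "child_and_adolescent",
      "instructions": {"CLI": 13.7, "DC": 13.5, "FK": 10.1, "FOG": 10.8, "FCST": 15.3, "mean": 12.7},
      "items": {"CLI": 11.9, "DC": 10.1, "FK": 9.9, "FOG": 14.6, "FCST": 13.4, "mean": 12.0}
    },
    {
      "name": "PROMIS Global Health 7+2",
      "target_age_min": 8, "target_age_max": 17, "n_items": 9, "age_group": "child_and_adolescent",
      "instructions": {"CLI": 14.1, "DC": 13.5, "FK": 10.1, "FOG": 10.8, "FCST": 15.3, "mean": 12.8},
      "items": {"CLI": 10.8, "DC": 10.2, "FK": 9.6, "FOG": 13.9, "FCST": 13.4, "mean": 11.6}
    },
    {
      "name": "QOLP-AV",
      "target_age_min": 14, "target_age_max": 20, "n_items": 72, "age_group": "adolescent",
      "instructions": {"CLI": 12.4, "DC": 11.9, "FK": 12.6, "FOG": 15.0, "FCST": 14.2, "mean": 13.2},
      "items": {"CLI": 10.6, "DC": 11.4, "FK": 9.7, "FOG": 12.2, "FCST": 15.2, "mean": 11.8}
    },
    {
      "name": "TACQOL",
      "target_age_min": 8, "target_age_max": 15, "n_items": 63, "age_group": "child_and_adolescent",
      "instructions": {"CLI": 11.6, "DC": 10.2, "FK": 9.2, "FOG": 11.4, "FCST": 13.5, "mean": 11.2},
      "items": {"CLI": 13.1, "DC": 11.2, "FK": 10.2, "FOG": 12.1, "FCST": 15.2, "mean": 12.4}
    },
    {
      "name": "YQOL-R",
      "target_age_min": 11, "target_age_max": 18, "n_items": 57, "age_group": "adolescent",
      "instructions": {"CLI": 14.3, "DC": 10.6, "FK": 11.0, "FOG": 12.5, "FCST": 14.8, "mean": 12.6},
      "items": {"CLI": 11.9, "DC": 10.1, "FK": 10.5, "FOG": 12.1, "FCST": 14.5, "mean": 11.8}
    },
    {
      "name": "YQOL-SF",
      "target_age_min": 11, "target_age_max": 18, "n_items": 16, "age_group": "adolescent",
      "instructions": {"CLI": 14.1, "DC": 10.6, "FK": 11.1, "FOG": 13.0, "FCST": 14.7, "mean": 12.7},
      "items": {"CLI": 11.6, "DC": 10.0, "FK": 10.6, "FOG": 12.3, "FCST": 14.5, "mean": 11.8}
    },
    {
      "name": "16D",
      "target_age_min": 12, "target_age_max": 15, "n_items": 16, "age_group": "adolescent",
      "instructions": {"CLI": 12.7, "DC": 9.8, "FK": 9.0, "FOG": 12.1, "FCST": 13.5, "mean": 11.4},
      "items": {"CLI": 11.7, "DC": 10.1, "FK": 10.3, "FOG": 12.5, "FCST": 14.7, "mean": 11.9}
    },
    {
      "name": "17D",
      "target_age_min": 8, "target_age_max": 11, "n_items": 17, "age_group": "child",
      "instructions": {"CLI": 12.7, "DC": 10.3, "FK": 8.3, "FOG": 10.8, "FCST": 13.9, "mean": 11.2},
      "items": {"CLI": 9.6, "DC": 11.9, "FK": 8.3, "FOG": 10.6, "FCST": 14.0, "mean": 10.9}
    }
  ]
}
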