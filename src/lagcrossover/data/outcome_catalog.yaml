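# Mutually exclusive broad-category (organ-system) and cause-specific
# mortality outcomes, as ICD-10 three-character code ranges (inclusive).
# External-cause handling: most of blocks V-Y is excluded from the
# non-accidental analysis set; intentional self-harm and assault
# (X60-Y09) are retained.
name: organ-system-mortality-outcomes
retained_external:
  - [X60, Y09]
excluded_external:
  - [V01, X59]
  - [Y10, Y98]
broad:
  Circulatory System:
    - [I00, I99]
  Digestive system:
    - [K00, K93]
  Respiratory system:
    - [J00, J99]
  Genitourinary:
    - [N00, N99]
  Nervous system:
    - [G00, G99]
  Intentional self-harm:
    - [X60, X84]
  Mental and behavioral:
    - [F00, F99]
specific:
  Acute ischemic heart disease:
    broad: Circulatory System
    ranges:
      - [I20, I22]
      - [I24, I24]
  Diseases of the liver:
    broad: Digestive system
    ranges:
      - [K70, K77]
  Chronic respiratory disease:
    broad: Respiratory system
    ranges:
      - [J40, J47]
  Hypertensive diseases:
    broad: Circulatory System
    ranges:
      - [I10, I15]
  Influenza and Pneumonia:
    broad: Respiratory system
    ranges:
      - [J09, J18]
  Renal failure:
    broad: Genitourinary
    ranges:
      - [N17, N19]
  Other forms of heart disease:
    broad: Circulatory System
    ranges:
      - [I30, I52]
  Stroke hemorrhagic:
    broad: Circulatory System
    ranges:
      - [I60, I62]
  Chronic ischemic heart disease:
    broad: Circulatory System
    ranges:
      - [I25, I25]
  Disorders of gallbladder, biliary tract, and pancreas:
    broad: Digestive system
    ranges:
      - [K80, K87]
  Diseases of esophagus, stomach and duodenum:
    broad: Digestive system
    ranges:
      - [K20, K31]
  Stroke ischemic:
    broad: Circulatory System
    ranges:
      - [I63, I63]
  Suicides:
    broad: Intentional self-harm
    ranges:
      - [X60, X84]
  Pulmonary heart disease:
    broad: Circulatory System
    ranges:
      - [I26, I28]
  Diseases of the arteries:
    broad: Circulatory System
    ranges:
      - [I70, I79]
  Chronic rheumatic heart diseases:
    broad: Circulatory System
    ranges:
      - [I05, I09]
  Extrapyramidal and movement disorders:
    broad: Nervous system
    ranges:
      - [G20, G26]
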