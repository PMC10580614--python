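"""ICD-10 cause classification and analysis-set filtering.

Shows how codes map to the mutually exclusive broad-category and
cause-specific outcomes, and how records are filtered with reasons.
"""

import pandas as pd

import lagcrossover as lc

catalog = lc.load_default_catalog()
for code in ["I21.4", "K70", "J18", "X70", "I23", "E11", "V02"]:
    c = lc.classify_cause(code, catalog)
    print(f"{code:6s} -> {c.status:8s} broad={c.broad!r} specific={c.specific!r}")

records = pd.DataFrame(
    {
        "death_date": ["2004-03-01", "2004-01-15", "2005-06-01", "2005-06-01"],
        "locality_id": "L1",
        "icd10": ["I21", "I21", "V02", "K70"],
        "age_years": [70, 70, 40, 17],
        "sex": "male", "education": "primary", "insurance": "none",
        "job_category": "not-employed",
    }
)
analysis, excl = lc.filter_records(records, "2004-02-01", "2019-12-31")
print(f"\nretained {len(analysis)} of {len(records)}; exclusions:")
print(excl.to_string(index=False))
# the retained record also carries its outcome labels:
print(analysis[["icd10", "broad", "specific"]].to_string(index=False))
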