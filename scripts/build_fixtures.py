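"""Build the bundled fixture CSVs and their sha256 manifest.

Run from the repository root: python scripts/build_fixtures.py
"""

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

DATA = Path(__file__).resolve().parents[1] / "src" / "growthineq" / "data"
DATA.mkdir(exist_ok=True)

T = 1826.0  # grid horizon: 60 months in days

AGES = [0, 30, 61, 91, 122, 152, 183, 274, 365, 456, 548, 639, 730,
        913, 1096, 1278, 1461, 1644, 1826]
LENGTHS = list(range(40, 130, 5))


def m_len(t, sex):
    base, gain = (50.0, 53.0) if sex == "male" else (49.2, 52.2)
    return base + gain * np.sqrt(t / T)


def m_bmi(t, sex):
    m = 13.3 + 4.0 * (t / 183.0) * np.exp(1.0 - t / 183.0)
    return m if sex == "male" else 0.98 * m


def l_bmi(t):
    return 1.0 - 1.2 * t / T


def s_len(t):
    # birth sizes vary more (gestational-age scatter); tapers with age
    return 0.05 - 0.013 * t / T


def s_bmi(t):
    return 0.13 - 0.04 * t / T


def t_of_length(x, sex):
    base, gain = (50.0, 53.0) if sex == "male" else (49.2, 52.2)
    return T * max((x - base) / gain, 0.0) ** 2


rows = []
for sex in ("male", "female"):
    for t in AGES:
        rows.append(("length_height_for_age", sex, float(t), 1.0,
                     round(m_len(t, sex), 4), round(s_len(t), 5)))
    for t in AGES:
        rows.append(("bmi_for_age", sex, float(t), round(l_bmi(t), 5),
                     round(m_bmi(t, sex), 4), round(s_bmi(t), 5)))
    for t in AGES:
        # weight median consistent with median BMI at median length
        m_w = m_bmi(t, sex) * (m_len(t, sex) / 100.0) ** 2
        rows.append(("weight_for_age", sex, float(t),
                     round(0.3 - 0.1 * t / T, 5), round(m_w, 4),
                     round(0.11 + 0.02 * t / T, 5)))
    for x in LENGTHS:
        t = t_of_length(x, sex)
        m_w = m_bmi(t, sex) * (x / 100.0) ** 2
        rows.append(("weight_for_length_height", sex, float(x), -0.2,
                     round(m_w, 4), 0.09))

ref = pd.DataFrame(rows, columns=["indicator", "sex", "index_value", "L", "M", "S"])
ref.to_csv(DATA / "growth_reference_synthetic.csv", index=False)

# --- toy cohort: 50 children x 4 visits, no attrition, fixed seed ------------
import sys
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from growthineq.anthropometry import GrowthReference
from growthineq.synthetic import CohortConfig, generate_cohort, write_cohort_csv

cfg = CohortConfig(cohort_label="toy", n_births=50, attrition_rate=0.0, seed=7321)
frame = generate_cohort(cfg, GrowthReference(ref))
frame = frame.round({"weight_kg": 4, "length_cm": 3, "income": 2})
write_cohort_csv(frame, DATA / "toy_cohort_synthetic.csv")

# --- published summary tables ------------------------------------------------
# Overall prevalence (%) with case counts by cohort and visit, plus the printed
# cross-cohort p-values; (-) cells are omitted rows.
P = "published prevalence-by-cohort table"
prev_rows = [
    # visit, indicator, cohort, prevalence_pct, cases, visit_n, p_value
    ("birth", "underweight", 1982, 7.1, 418, 5914, "0.118"),
    ("birth", "underweight", 1993, 7.8, 405, 5249, "0.118"),
    ("birth", "underweight", 2004, 7.9, 332, 4231, "0.118"),
    ("birth", "stunting", 1993, 9.3, 476, 5249, "<0.001"),
    ("birth", "stunting", 2004, 12.4, 513, 4231, "<0.001"),
    ("birth", "wasting", 1993, 3.6, 179, 5249, "<0.001"),
    ("birth", "wasting", 2004, 1.3, 50, 4231, "<0.001"),
    ("birth", "overweight", 1993, 2.2, 112, 5249, "0.261"),
    ("birth", "overweight", 2004, 2.5, 105, 4231, "0.261"),
    ("1y", "underweight", 1982, 4.0, 58, 1457, "0.001"),
    ("1y", "underweight", 1993, 2.6, 65, 1361, "0.001"),
    ("1y", "underweight", 2004, 2.2, 86, 3907, "0.001"),
    ("1y", "stunting", 1982, 8.5, 123, 1457, "0.001"),
    ("1y", "stunting", 1993, 9.2, 182, 1361, "0.001"),
    ("1y", "stunting", 2004, 6.0, 232, 3907, "0.001"),
    ("1y", "wasting", 1982, 2.1, 30, 1457, "<0.001"),
    ("1y", "wasting", 1993, 0.7, 17, 1361, "<0.001"),
    ("1y", "wasting", 2004, 0.6, 25, 3907, "<0.001"),
    ("1y", "overweight", 1982, 6.9, 101, 1457, "0.107"),
    ("1y", "overweight", 1993, 10.8, 129, 1361, "0.107"),
    ("1y", "overweight", 2004, 8.9, 347, 3907, "0.107"),
    ("2y", "underweight", 1982, 3.1, 154, 4939, "0.001"),
    ("2y", "underweight", 2004, 2.0, 77, 3869, "0.001"),
    ("2y", "stunting", 1982, 13.9, 687, 4939, "<0.001"),
    ("2y", "stunting", 2004, 5.0, 192, 3869, "<0.001"),
    ("2y", "wasting", 1982, 0.8, 37, 4939, "0.995"),
    ("2y", "wasting", 2004, 0.8, 29, 3869, "0.995"),
    ("2y", "overweight", 1982, 8.5, 418, 4939, "0.781"),
    ("2y", "overweight", 2004, 8.3, 320, 3869, "0.781"),
    ("4y", "underweight", 1982, 2.3, 109, 4742, "0.051"),
    ("4y", "underweight", 1993, 2.4, 39, 1243, "0.051"),
    ("4y", "underweight", 2004, 1.7, 64, 3799, "0.051"),
    ("4y", "stunting", 1982, 10.9, 518, 4742, "<0.001"),
    ("4y", "stunting", 1993, 5.3, 92, 1243, "<0.001"),
    ("4y", "stunting", 2004, 3.6, 138, 3799, "<0.001"),
    ("4y", "wasting", 1982, 0.3, 16, 4742, "0.130"),
    ("4y", "wasting", 1993, 0.4, 10, 1243, "0.130"),
    ("4y", "wasting", 2004, 0.6, 21, 3799, "0.130"),
    ("4y", "overweight", 1982, 7.6, 358, 4742, "<0.001"),
    ("4y", "overweight", 1993, 10.7, 121, 1243, "<0.001"),
    ("4y", "overweight", 2004, 12.3, 463, 3799, "<0.001"),
]
prev = pd.DataFrame(prev_rows, columns=["visit", "indicator", "cohort",
                                        "prevalence_pct", "cases", "visit_n",
                                        "p_value"])
prev["provenance"] = (P + ", " + prev["visit"] + " " + prev["indicator"]
                      + " row, " + prev["cohort"].astype(str) + " cohort")
prev.to_csv(DATA / "prevalence_by_cohort.csv", index=False)


def quintile_table(name, rows, label):
    df = pd.DataFrame(rows, columns=["cohort", "visit", "q1", "q2", "q3", "q4",
                                     "q5", "sii", "sii_lo", "sii_hi",
                                     "rii", "rii_lo", "rii_hi"])
    df["provenance"] = (f"published {label}-by-quintile table, "
                        + df["cohort"].astype(str) + " cohort, "
                        + df["visit"] + " row")
    df.to_csv(DATA / name, index=False)


quintile_table("stunting_by_income_quintile.csv", [
    (1982, "1y", 19.8, 10.6, 6.0, 5.5, 3.6, -16.80, -21.80, -11.82, 0.10, 0.04, 0.21),
    (1993, "1y", 16.8, 11.5, 6.9, 5.4, 4.8, -18.52, -24.84, -12.19, 0.19, 0.11, 0.34),
    (2004, "1y", 8.1, 9.1, 5.7, 3.8, 3.1, -7.60, -10.23, -4.98, 0.25, 0.15, 0.40),
    (1982, "2y", 28.9, 21.8, 10.1, 7.1, 3.6, -32.04, -35.34, -28.74, 0.05, 0.04, 0.07),
    (2004, "2y", 8.8, 8.4, 3.8, 2.4, 1.5, -10.34, -12.74, -7.93, 0.09, 0.05, 0.17),
    (1982, "4y", 26.0, 16.0, 6.3, 5.3, 2.7, -27.79, -30.83, -24.75, 0.04, 0.03, 0.06),
    (1993, "4y", 11.8, 4.6, 5.5, 2.3, 2.6, -14.24, -19.34, -9.15, 0.11, 0.05, 0.25),
    (2004, "4y", 6.7, 5.3, 3.1, 2.0, 1.1, -7.21, -9.30, -5.11, 0.11, 0.06, 0.21),
], "stunting")

quintile_table("overweight_by_income_quintile.csv", [
    (1982, "1y", 5.0, 7.9, 4.4, 7.8, 9.2, 3.93, -0.69, 8.55, 1.85, 0.90, 3.80),
    (1993, "1y", 12.9, 9.9, 8.0, 14.4, 9.1, -0.14, -5.66, 5.38, 0.98, 0.52, 1.87),
    (2004, "1y", 9.2, 8.1, 9.5, 9.5, 8.4, -0.12, -3.29, 3.05, 0.99, 0.67, 1.46),
    (1982, "2y", 7.2, 6.2, 8.5, 9.9, 10.5, 5.05, 2.31, 7.80, 1.93, 1.35, 2.76),
    (2004, "2y", 7.5, 8.2, 7.0, 8.9, 10.0, 2.86, -0.22, 5.94, 1.46, 0.97, 2.18),
    (1982, "4y", 5.3, 6.4, 5.4, 9.8, 10.8, 7.18, 4.52, 9.84, 2.84, 1.92, 4.20),
    (1993, "4y", 6.0, 10.1, 8.7, 13.5, 16.0, 12.69, 6.83, 18.54, 4.36, 2.18, 8.73),
    (2004, "4y", 8.7, 10.3, 12.6, 14.9, 15.2, 8.80, 5.09, 12.51, 2.27, 1.61, 3.22),
], "overweight")

# --- manifest ----------------------------------------------------------------
names = {
    "growth_reference_synthetic": "growth_reference_synthetic.csv",
    "toy_cohort_synthetic": "toy_cohort_synthetic.csv",
    "prevalence_by_cohort": "prevalence_by_cohort.csv",
    "stunting_by_income_quintile": "stunting_by_income_quintile.csv",
    "overweight_by_income_quintile": "overweight_by_income_quintile.csv",
}
manifest = []
for name, fname in names.items():
    digest = hashlib.sha256((DATA / fname).read_bytes()).hexdigest()
    manifest.append({"name": name, "path": fname, "sha256": digest})
with open(DATA / "manifest.json", "w") as fh:
    json.dump(manifest, fh, indent=1)
    fh.write("\n")
print("fixtures written:", [m["path"] for m in manifest])
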