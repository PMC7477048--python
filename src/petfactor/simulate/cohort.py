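"""Clinical covariate tables for simulated head-and-neck cohorts.

Category frequencies follow a locally advanced HNSCC chemoradiotherapy
population: mostly T2-T4 / N2 disease, roughly one third HPV-positive,
heavy smoking history.  Pack-years are drawn log-normally (median ~23).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ClinicalCohortSpec:
    n_patients: int = 103
    t_stage_probs: tuple[float, ...] = (0.447, 0.233, 0.320)   # T2, T3, T4
    n_stage_probs: tuple[float, ...] = (0.136, 0.126, 0.728, 0.010)  # N0..N3
    hpv_positive_rate: float = 0.379
    cisplatin_rate: float = 0.854
    smoking_log_median: float = np.log(23.0)
    smoking_log_sd: float = 0.55
    seed: int = 0


def generate_clinical_table(spec: ClinicalCohortSpec) -> pd.DataFrame:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    t_stage = rng.choice([2, 3, 4], size=n, p=spec.t_stage_probs)
    n_stage = rng.choice([0, 1, 2, 3], size=n, p=spec.n_stage_probs)
    hpv = (rng.uniform(size=n) < spec.hpv_positive_rate).astype(int)
    treatment = np.where(rng.uniform(size=n) < spec.cisplatin_rate,
                         "cisplatin", "cetuximab")
    smoking = np.exp(rng.normal(spec.smoking_log_median, spec.smoking_log_sd, size=n))
    alcohol = rng.choice([0, 1, 2, 3, 4], size=n, p=[0.1, 0.25, 0.35, 0.2, 0.1])
    return pd.DataFrame(
        {
            "t_stage": t_stage,
            "n_stage": n_stage,
            "hpv": hpv,
            "smoking_py": np.round(smoking, 1),
            "alcohol_score": alcohol,
            "treatment": treatment,
        }
    )
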