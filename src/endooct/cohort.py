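"""Synthetic longitudinal cohorts of vessel-density and thickness metrics.

The generator emulates a four-visit laser-treatment study in which each
patient is imaged at four vaginal locations (distal/proximal x
anterior/posterior) per visit.  Blood vessel density (BVD, area fraction)
and vaginal epithelial thickness (VET, um) increase over the visits;
clinician (VHI) and patient (VSQ) scores are generated from the same
latent tissue-health signal so that their Pearson correlations with the
objective metrics approach configured magnitudes.

Default effect sizes: grand-mean BVD rises 21.7% -> 29.6% and grand-mean
VET 123.3 um -> 160.3 um from the first to the fourth visit, with the
proximal-anterior location offset upward in BVD.  VHI is an integer score
on the 5-25 scale (five 1-5 items); VSQ is oriented so that higher means
worse, giving a negative correlation with tissue health — downstream
comparisons use correlation magnitudes.

The output is a tidy long-format table (pandas DataFrame) with columns
``patient_id, visit, location, bvd, vet_um, vhi, vsq`` — one record per
(patient, visit, location).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LOCATIONS", "VISITS", "ScoreModel", "CohortEffectModel", "generate_cohort"]

LOCATIONS = ("da", "dp", "pa", "pp")
VISITS = (1, 2, 3, 4)


@dataclass(frozen=True)
class ScoreModel:
    """Latent-health score model linking VHI/VSQ to the objective metrics.

    ``r_vhi_vet`` / ``r_vsq_vet`` are the target Pearson magnitudes of the
    scores with VET; ``r_vhi_vsq`` the target between the two scores; and
    ``vet_bvd_corr`` the pooled VET-BVD correlation, which fixes the
    implied score-BVD magnitudes (r_score_bvd = r_score_vet * vet_bvd_corr).
    """

    r_vhi_vet: float = 0.853
    r_vsq_vet: float = 0.721
    r_vhi_vsq: float = 0.754
    vet_bvd_corr: float = 0.44
    vhi_mean: float = 15.0
    vhi_sd: float = 3.2
    vsq_mean: float = 10.0
    vsq_sd: float = 4.0

    def __post_init__(self):
        for name in ("r_vhi_vet", "r_vsq_vet", "r_vhi_vsq", "vet_bvd_corr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class CohortEffectModel:
    """Generating parameters of a synthetic cohort.

    Visit means interpolate linearly from baseline to final over the four
    visits (monotone under the defaults).  Per-location offsets are
    constant across visits and sum to zero so the grand mean matches the
    stated trajectory.  Between-patient and within-patient SDs control a
    shared patient random effect and record-level noise.
    """

    n_patients: int = 25
    baseline_bvd_mean: float = 0.217
    final_bvd_mean: float = 0.296
    baseline_vet_mean: float = 123.3
    final_vet_mean: float = 160.3
    bvd_location_offsets: dict = field(
        default_factory=lambda: {"da": -0.003, "dp": -0.003, "pa": 0.009, "pp": -0.003}
    )
    vet_location_offsets: dict = field(
        default_factory=lambda: {"da": 0.0, "dp": 0.0, "pa": 0.0, "pp": 0.0}
    )
    bvd_between_sd: float = 0.04
    bvd_within_sd: float = 0.03
    vet_between_sd: float = 20.0
    vet_within_sd: float = 12.0
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_bvd_mean", "final_bvd_mean"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be a fraction in (0, 1), got {v}")
        for name in ("bvd_between_sd", "bvd_within_sd", "vet_between_sd", "vet_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_vet_mean < 0 or self.final_vet_mean < 0:
            raise ValueError("VET means must be >= 0")

    def visit_mean_bvd(self, visit: int) -> float:
        return self.baseline_bvd_mean + (self.final_bvd_mean - self.baseline_bvd_mean) * (visit - 1) / 3.0

    def visit_mean_vet(self, visit: int) -> float:
        return self.baseline_vet_mean + (self.final_vet_mean - self.baseline_vet_mean) * (visit - 1) / 3.0


def _cell_means(model: CohortEffectModel):
    """Fixed (visit, location) cell means for both metrics, pooled order."""
    vet = np.array([
        model.visit_mean_vet(v) + model.vet_location_offsets[loc]
        for v in VISITS for loc in LOCATIONS
    ])
    bvd = np.array([
        model.visit_mean_bvd(v) + model.bvd_location_offsets[loc]
        for v in VISITS for loc in LOCATIONS
    ])
    return vet, bvd


def generate_cohort(model: CohortEffectModel) -> pd.DataFrame:
    """Draw a synthetic study table from a `CohortEffectModel`.

    Returns one record per (patient, visit, location).  Sample means
    converge to the model's cell means as ``n_patients`` grows, and the
    pooled Pearson correlations of VHI/VSQ with VET and BVD approach the
    magnitudes configured in the score model (up to integer-score
    discretization).  Identical models (including seed) give identical
    tables.
    """
    if model.n_patients < 2:
        raise ValueError("n_patients must be >= 2 (variance undefined otherwise)")
    rng = np.random.default_rng(model.seed)
    sm = model.score_model

    cell_vet, cell_bvd = _cell_means(model)
    n_cells = len(cell_vet)

    # analytic pooled moments of the generated metrics (cells equally likely)
    var_trend_vet = cell_vet.var()
    var_trend_bvd = cell_bvd.var()
    cov_trend = np.mean((cell_vet - cell_vet.mean()) * (cell_bvd - cell_bvd.mean()))
    a_v, b_v = model.vet_between_sd, model.vet_within_sd
    a_b, b_b = model.bvd_between_sd, model.bvd_within_sd
    s_vet = np.sqrt(var_trend_vet + a_v**2 + b_v**2)
    s_bvd = np.sqrt(var_trend_bvd + a_b**2 + b_b**2)

    # correlation rho applied to both random components so the pooled
    # VET-BVD correlation lands at the configured value
    random_cov = a_v * a_b + b_v * b_b
    if random_cov > 0:
        rho = (sm.vet_bvd_corr * s_vet * s_bvd - cov_trend) / random_cov
        rho = float(np.clip(rho, -1.0, 1.0))
    else:
        rho = 0.0

    n = model.n_patients
    # patient random effects, shared between metrics with correlation rho
    u_v = rng.standard_normal(n)
    u_b = rho * u_v + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)

    records = []
    cell_idx = 0
    w_v_all = rng.standard_normal((n, n_cells))
    w_b_raw = rng.standard_normal((n, n_cells))
    w_b_all = rho * w_v_all + np.sqrt(max(0.0, 1 - rho**2)) * w_b_raw

    vet_vals = np.empty((n, n_cells))
    bvd_vals = np.empty((n, n_cells))
    for ci in range(n_cells):
        vet_vals[:, ci] = cell_vet[ci] + a_v * u_v + b_v * w_v_all[:, ci]
        bvd_vals[:, ci] = cell_bvd[ci] + a_b * u_b + b_b * w_b_all[:, ci]
    vet_vals = np.maximum(vet_vals, 0.0)
    bvd_vals = np.clip(bvd_vals, 1e-3, 0.999)

    # scores from the standardized VET signal (the latent-health proxy)
    if s_vet > 0:
        z_vet = (vet_vals - cell_vet.mean()) / s_vet
    else:
        z_vet = np.zeros_like(vet_vals)
    r1, r2 = sm.r_vhi_vet, sm.r_vsq_vet
    c1, c2 = np.sqrt(1 - r1**2), np.sqrt(1 - r2**2)
    if c1 > 0 and c2 > 0:
        rho_eta = float(np.clip((sm.r_vhi_vsq - r1 * r2) / (c1 * c2), -1.0, 1.0))
    else:
        rho_eta = 0.0
    eta1 = rng.standard_normal((n, n_cells))
    eta2 = rho_eta * eta1 + np.sqrt(max(0.0, 1 - rho_eta**2)) * rng.standard_normal((n, n_cells))
    vhi_latent = r1 * z_vet + c1 * eta1
    vsq_latent = r2 * z_vet + c2 * eta2  # health-oriented; flipped below

    vhi = np.clip(np.rint(sm.vhi_mean + sm.vhi_sd * vhi_latent), 5, 25).astype(int)
    vsq = np.clip(np.rint(sm.vsq_mean - sm.vsq_sd * vsq_latent), 0, 21).astype(int)

    cell_idx = 0
    for v in VISITS:
        for loc in LOCATIONS:
            for p in range(n):
                records.append({
                    "patient_id": f"P{p + 1:03d}",
                    "visit": v,
                    "location": loc,
                    "bvd": bvd_vals[p, cell_idx],
                    "vet_um": vet_vals[p, cell_idx],
                    "vhi": vhi[p, cell_idx],
                    "vsq": vsq[p, cell_idx],
                })
            cell_idx += 1

    df = pd.DataFrame.from_records(records)
    df.attrs["model"] = model
    return df
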