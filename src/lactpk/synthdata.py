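"""Synthetic "observed" study data: sparse sampling, residual error, LLOQ
censoring, and infant-daily-dose recovery from milk observations.

The generator emulates the statistical structure of a clinical lactation
dataset — a handful of maternal plasma/milk samples per subject with
combined proportional + additive assay error, reported as below the limit
of quantitation (BLQ) when the observed value falls under the LLOQ of
1-2 ng/mL — so the whole analysis loop (milk exposure -> infant daily dose
-> infant simulation) can be exercised without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ConcentrationProfile

__all__ = ["ErrorModel", "ObservationSet", "synth_observations", "recover_idd"]

#: default sampling offsets within a dosing day (h): pre-dose through trough
DEFAULT_SAMPLE_OFFSETS = (0.0, 2.0, 4.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class ErrorModel:
    """Combined residual error: obs = conc*(1 + eps_prop) + eps_add."""

    cv_prop: float = 0.20
    sd_add: float = 0.05  # ng/mL

    def __post_init__(self) -> None:
        if self.cv_prop < 0 or self.sd_add < 0:
            raise ValueError("error magnitudes must be non-negative")


@dataclass
class ObservationSet:
    """Sparse observations with LLOQ censoring, serializable to CSV."""

    records: pd.DataFrame  # subject_id, matrix, time_h, conc_ng_ml, blq_flag
    lloq: float
    error: ErrorModel
    seed: int

    def quantified(self) -> pd.DataFrame:
        return self.records[~self.records["blq_flag"]]

    def fraction_blq(self) -> float:
        return float(self.records["blq_flag"].mean())

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# lloq_ng_ml={self.lloq} seed={self.seed} "
                     f"cv_prop={self.error.cv_prop} sd_add={self.error.sd_add}\n")
            self.records.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            records = pd.read_csv(fh)
        return cls(
            records=records,
            lloq=float(meta["lloq_ng_ml"]),
            error=ErrorModel(cv_prop=float(meta["cv_prop"]),
                             sd_add=float(meta["sd_add"])),
            seed=int(meta["seed"]),
        )


def synth_observations(profile: ConcentrationProfile,
                       sample_times: np.ndarray,
                       error: ErrorModel = ErrorModel(),
                       lloq: float = 1.0,
                       seed: int = 0,
                       subject_id: int = 0,
                       matrix: str = "plasma",
                       scale: float = 1.0) -> ObservationSet:
    """Sample a simulated profile at sparse times with assay error.

    ``scale`` multiplies the profile before sampling (e.g. an M/P ratio to
    turn a plasma profile into a milk profile).  An observation is flagged
    BLQ exactly when its pre-censoring value falls below the LLOQ;
    quantified concentrations are therefore always >= LLOQ.
    """
    if lloq < 0:
        raise ValueError("LLOQ must be non-negative")
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.min() < profile.times[0] - 1e-9 or \
            sample_times.max() > profile.times[-1] + 1e-9:
        raise ValueError("sample times must lie within the simulated span")
    rng = np.random.default_rng(seed)
    truth = scale * np.interp(sample_times, profile.times, profile.conc)
    obs = truth * (1.0 + error.cv_prop * rng.standard_normal(truth.size)) \
        + error.sd_add * rng.standard_normal(truth.size)
    blq = obs < lloq
    records = pd.DataFrame({
        "subject_id": subject_id,
        "matrix": matrix,
        "time_h": sample_times,
        "conc_ng_ml": np.where(blq, np.nan, obs),
        "blq_flag": blq,
    })
    return ObservationSet(records=records, lloq=lloq, error=error, seed=seed)


def recover_idd(milk_obs: ObservationSet, intake: float) -> float:
    """Estimate the infant daily dose (ug/kg/day) from milk observations.

    Time-averaged milk concentration by trapezoid over the quantified
    samples, times the milk intake (mL/kg/day).
    """
    if intake <= 0:
        raise ValueError("milk intake must be positive")
    q = milk_obs.quantified()
    if len(q) < 2:
        raise ValueError(
            "need at least two quantified milk samples to estimate the IDD"
        )
    q = q.sort_values("time_h")
    t = q["time_h"].to_numpy()
    c = q["conc_ng_ml"].to_numpy()
    cavg = np.trapezoid(c, t) / (t[-1] - t[0])
    return float(cavg * intake / 1000.0)
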