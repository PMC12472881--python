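"""Synthetic preclinical study generator.

Emulates the reference study designs: subcutaneous dosing over 0.1-300
mg/kg, destructive terminal sampling with n = 3 animals per time point,
concentration measurements in plasma and tissues, and baseline-normalized
liver mRNA / plasma target protein.  Concentration replicates carry
multiplicative lognormal residual noise (unbiased in log space); PD
replicates carry additive Gaussian noise in percentage points, truncated to
[0, 120]% to mimic assay normalization.  The generating truth (parameter
values and noiseless curves) is returned alongside the noisy observations
for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate_fit import ObservedSeries
from .parameters import Parameterization
from .physiology import TISSUES
from .simulate import DoseRegimen, OBSERVABLE_UNITS, simulate

#: sampling grids resolving the absorption peak, the rapid decline, and the
#: slow redistribution phase out to six weeks
DEFAULT_PLASMA_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 96.0,
                        168.0, 336.0, 672.0, 1008.0)
DEFAULT_TISSUE_TIMES = (1.0, 4.0, 8.0, 24.0, 48.0, 96.0, 168.0, 336.0,
                        672.0, 1008.0)
DEFAULT_PD_TIMES = (24.0, 96.0, 168.0, 336.0, 672.0, 1008.0)


@dataclass(frozen=True)
class StudyDesign:
    """Dose groups, per-biospecimen sampling schedule, and the noise model."""

    species: str
    compound: str
    doses_mg_per_kg: tuple[float, ...]
    sampling_times: dict[str, tuple[float, ...]]
    n_per_point: int = 3
    conc_cv: float = 0.20
    pd_sd_pct: float = 5.0
    pd_truncate: tuple[float, float] | None = (0.0, 120.0)

    def __post_init__(self) -> None:
        if self.n_per_point < 1:
            raise ValueError("n_per_point must be >= 1")
        if self.conc_cv < 0 or self.pd_sd_pct < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not self.doses_mg_per_kg or any(
                d <= 0 for d in self.doses_mg_per_kg):
            raise ValueError("doses must be positive")
        valid = {"plasma", "mrna", "protein"} | set(TISSUES)
        bad = set(self.sampling_times) - valid
        if bad:
            raise ValueError(f"unknown biospecimens: {sorted(bad)}")

    @property
    def horizon(self) -> float:
        return max(max(ts) for ts in self.sampling_times.values())


def mouse_sirna1_design(doses: tuple[float, ...] = (3.0, 10.0, 100.0),
                        biospecimens: tuple[str, ...] = (
                            "plasma", "liver", "kidney", "gonads", "lung",
                            "spleen", "mrna"),
                        **kwargs) -> StudyDesign:
    """The mouse siRNA-1 study menu: plasma, liver, kidney, gonads, lung,
    spleen and liver mRNA at 3/10/100 mg/kg, n = 3 per time point."""
    times = {}
    for b in biospecimens:
        if b == "plasma":
            times[b] = DEFAULT_PLASMA_TIMES
        elif b in ("mrna", "protein"):
            times[b] = DEFAULT_PD_TIMES
        else:
            times[b] = DEFAULT_TISSUE_TIMES
    return StudyDesign(species="mouse", compound="siRNA-1",
                       doses_mg_per_kg=tuple(doses), sampling_times=times,
                       **kwargs)


@dataclass
class StudyTruth:
    """Generating truth: parameterization and noiseless sampled curves."""

    parameterization: Parameterization
    curves: dict[tuple[float, str], np.ndarray]  # (dose, biospecimen) -> values
    times: dict[tuple[float, str], np.ndarray]


def generate_study(
    design: StudyDesign,
    param: Parameterization,
    seed: int,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> tuple[list[ObservedSeries], StudyTruth]:
    """Simulate true curves and emit noisy destructive-sampling replicates.

    Each observation time yields ``n_per_point`` independent replicate values
    (different animals).  Fully deterministic given the seed.
    """
    if param.species.species != design.species:
        raise ValueError("design species does not match parameterization")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(design.conc_cv ** 2))

    all_times = np.array(sorted({t for ts in design.sampling_times.values()
                                 for t in ts}))
    observed: list[ObservedSeries] = []
    truth = StudyTruth(parameterization=param, curves={}, times={})
    for dose in design.doses_mg_per_kg:
        regimen = DoseRegimen(dose=dose, compound_id=param.compound.compound_id)
        res = simulate(param, regimen, t_end=float(all_times.max()),
                       t_eval=all_times, rtol=rtol, atol=atol, method=method)
        for bio, ts in design.sampling_times.items():
            ts_arr = np.asarray(ts, dtype=float)
            true_vals = np.interp(ts_arr, res.time, res.curves[bio])
            truth.curves[(dose, bio)] = true_vals
            truth.times[(dose, bio)] = ts_arr
            rep_t, rep_v = [], []
            for t, v in zip(ts_arr, true_vals):
                for _ in range(design.n_per_point):
                    if bio in ("mrna", "protein"):
                        obs = v + rng.normal(0.0, design.pd_sd_pct)
                        if design.pd_truncate is not None:
                            obs = float(np.clip(obs, *design.pd_truncate))
                    else:
                        obs = v * np.exp(rng.normal(0.0, sigma))
                    rep_t.append(float(t))
                    rep_v.append(max(float(obs), 0.0))
            observed.append(ObservedSeries(
                compound=design.compound, species=design.species,
                dose_mg_per_kg=dose, biospecimen=bio,
                times=tuple(rep_t), values=tuple(rep_v),
                unit=OBSERVABLE_UNITS[bio], n=design.n_per_point))
    return observed, truth
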