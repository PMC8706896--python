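"""Synthetic study generators: maturation series, spike designs, RT grids.

These emulate the data a triple-quadrupole lipidomics study produces — a
peak-area table over a 13-point berry maturation series with five
biological replicates per point (three for the last two points), pooled
QC injections, per-class internal standards, multiplicative log-normal
noise and random missingness — with the planted truth returned alongside
so downstream estimators can be checked against it.  Class-level trends
are planted as linear-in-Brix log-abundance slopes: lyso-phospholipids
(LPC, LPE) and PE/PG/PI rise with ripening, CER/MG/LPG/DGDG/MGDG fall,
everything else stays flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import MRMTransition
from .rules import default_is_map

__all__ = [
    "MaturationDesign",
    "simulate_maturation",
    "simulate_spike_design",
    "simulate_rt_grid",
    "TREND_UP",
    "TREND_DOWN",
]

TREND_UP: tuple[str, ...] = ("LPC", "LPE", "PE", "PG", "PI")
TREND_DOWN: tuple[str, ...] = ("CER", "MG", "LPG", "DGDG", "MGDG")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


@dataclass(frozen=True)
class MaturationDesign:
    """Study layout and generative parameters of the maturation series."""

    n_points: int = 13
    replicates: tuple[int, ...] = (5,) * 11 + (3, 3)
    brix_start: float = 14.0
    brix_end: float = 22.0
    trend_up: tuple[str, ...] = TREND_UP
    trend_down: tuple[str, ...] = TREND_DOWN
    slope: float = 0.08          # log-abundance per degree Brix
    noise_cv: float = 0.10
    missing_rate: float = 0.05
    n_qc: int = 6
    baseline_log_mean: float = 11.5
    baseline_log_sd: float = 1.0
    weight_mg: tuple[float, float] = (90.0, 110.0)
    is_area: float = 1.0e6

    def __post_init__(self) -> None:
        if len(self.replicates) != self.n_points:
            raise ValueError(
                f"{self.n_points} time points but {len(self.replicates)} "
                "replicate counts"
            )

    def trend_sign(self, lipid_class: str) -> int:
        if lipid_class in self.trend_up:
            return 1
        if lipid_class in self.trend_down:
            return -1
        return 0

    @property
    def brix_trajectory(self) -> np.ndarray:
        return np.linspace(self.brix_start, self.brix_end, self.n_points)


def _compound_frame(compounds) -> pd.DataFrame:
    if isinstance(compounds, pd.DataFrame):
        df = compounds[["transition_id", "lipid_class"]].copy()
    elif compounds and isinstance(compounds[0], MRMTransition):
        df = pd.DataFrame(
            {
                "transition_id": [t.transition_id for t in compounds],
                "lipid_class": [t.lipid_class for t in compounds],
            }
        )
    else:
        df = pd.DataFrame(compounds, columns=["transition_id", "lipid_class"])
    return df.drop_duplicates("transition_id").reset_index(drop=True)


def simulate_maturation(
    design: MaturationDesign,
    compounds,
    seed: int = 0,
    is_map: dict[str, tuple[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a peak-area table for a maturation study.

    Parameters
    ----------
    design
        Study layout and noise model.
    compounds
        Analyte panel: MRMTransition list, (transition_id, lipid_class)
        pairs, or a DataFrame with those columns.
    is_map
        class -> (IS id, amount ug); defaults to the shipped standards.

    Returns ``(areas, samples, truth)``: a long area table (IS rows
    included, missing analyte areas as NaN), per-sample metadata, and the
    planted truth (per-compound slopes and the implied concentration
    matrix before missingness masking).
    """
    rng = np.random.default_rng(seed)
    panel = _compound_frame(compounds)
    present = set(panel["lipid_class"])
    for cls in design.trend_up + design.trend_down:
        if cls not in present:
            raise ValueError(f"trend class {cls!r} absent from the compound panel")
    is_map = is_map if is_map is not None else default_is_map()
    missing_is = present - set(is_map)
    if missing_is:
        raise KeyError(f"no internal standard for classes {sorted(missing_is)}")

    # per-compound generative parameters
    n_comp = len(panel)
    baseline = rng.normal(design.baseline_log_mean, design.baseline_log_sd, n_comp)
    sign = panel["lipid_class"].map(design.trend_sign).to_numpy()
    slopes = sign * design.slope * rng.uniform(0.5, 1.5, n_comp)

    # samples
    rows = []
    brix = design.brix_trajectory
    for p, (b, nrep) in enumerate(zip(brix, design.replicates), start=1):
        for r in range(1, nrep + 1):
            rows.append((f"MP{p:02d}_R{r}", b, p, r, "study"))
    for q in range(1, design.n_qc + 1):
        rows.append((f"QC{q}", float(np.mean(brix)), 0, q, "QC"))
    samples = pd.DataFrame(
        rows, columns=["sample", "brix", "maturation_point", "replicate", "role"]
    )
    samples["weight_mg"] = rng.uniform(*design.weight_mg, len(samples))

    study = samples[samples["role"] == "study"]
    brix_center = study["brix"].mean()

    # analyte areas: log-linear trend in Brix + multiplicative noise
    log_mu = baseline[None, :] + (
        (study["brix"].to_numpy() - brix_center)[:, None] * slopes[None, :]
    )
    study_areas = np.exp(log_mu) * _lognormal_factor(
        rng, design.noise_cv, log_mu.shape
    )
    # QC: pooled mean of the study samples, re-noised
    qc_mu = study_areas.mean(axis=0)
    qc = samples[samples["role"] == "QC"]
    qc_areas = qc_mu[None, :] * _lognormal_factor(
        rng, design.noise_cv, (len(qc), n_comp)
    )
    all_areas = np.vstack([study_areas, qc_areas])
    area = pd.DataFrame(
        all_areas,
        index=pd.Index(list(study["sample"]) + list(qc["sample"]), name="sample"),
        columns=panel["transition_id"],
    )

    # internal standards: nominally constant area, re-noised per sample
    needed = sorted({is_map[c][0] for c in present})
    is_wide = pd.DataFrame(
        design.is_area
        * _lognormal_factor(rng, design.noise_cv, (len(area.index), len(needed))),
        index=area.index,
        columns=needed,
    )

    # implied true concentrations under the realised IS areas (pre-masking)
    weights_g = samples.set_index("sample")["weight_mg"] / 1000.0
    amounts = panel["lipid_class"].map(lambda c: is_map[c][1]).to_numpy()
    is_ref = pd.DataFrame(
        {tid: is_wide[is_map[cls][0]]
         for tid, cls in zip(panel["transition_id"], panel["lipid_class"])}
    )
    conc_truth = area / is_ref * amounts[None, :]
    conc_truth = conc_truth.div(weights_g.loc[area.index], axis=0)

    # missingness mask on analyte areas
    if design.missing_rate > 0:
        mask = rng.random(area.shape) < design.missing_rate
        # keep at least one observed value per compound
        all_gone = mask.all(axis=0)
        mask[0, all_gone] = False
        area = area.mask(mask)
        conc_truth = conc_truth.mask(mask)

    long = (
        area.reset_index()
        .melt(id_vars="sample", var_name="transition_id", value_name="area")
        .merge(panel, on="transition_id")
    )

    is_df = (
        is_wide.reset_index()
        .melt(id_vars="sample", var_name="transition_id", value_name="area")
        .assign(lipid_class="IS")
    )
    areas_out = pd.concat([long, is_df], ignore_index=True)

    truth = {
        "slopes": pd.Series(slopes, index=panel["transition_id"], name="slope"),
        "baseline": pd.Series(
            baseline, index=panel["transition_id"], name="log_baseline"
        ),
        "trend_sign": {
            cls: design.trend_sign(cls) for cls in sorted(present)
        },
        "conc": conc_truth,
        "classes": panel.set_index("transition_id")["lipid_class"],
    }
    return areas_out, samples, truth


def simulate_spike_design(
    true_recovery: dict[str, float],
    levels: tuple[float, ...] = (0.1, 0.5, 1.0),
    replicates: int = 5,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Spiked-recovery design: measured = expected * recovery% * noise.

    One row per (class, level, replicate) with ``expected`` at the
    nominal spike level and the planted per-class recovery applied.
    """
    if any(lv <= 0 for lv in levels):
        raise ValueError(f"spike levels must be positive, got {levels}")
    rng = np.random.default_rng(seed)
    rows = []
    for cls in sorted(true_recovery):
        rec = true_recovery[cls] / 100.0
        for lv in levels:
            noise = _lognormal_factor(rng, noise_cv, replicates)
            for r in range(replicates):
                rows.append((cls, lv, r + 1, lv, lv * rec * noise[r]))
    return pd.DataFrame(
        rows, columns=["lipid_class", "level", "replicate", "expected", "measured"]
    )


def simulate_rt_grid(
    transitions: list[MRMTransition],
    species_lookup,
    *,
    per_carbon: float = 0.1,
    per_double_bond: float = 0.5,
    class_intercepts: dict[str, float] | None = None,
    base_intercept: float = 5.0,
) -> pd.DataFrame:
    """Clean retention-time grid for Kendrick-check fixtures.

    RT = intercept(class) + per_carbon * total C - per_double_bond *
    total DB, the class-wise monotone rule reversed-phase separation
    follows.  ``species_lookup`` maps a transition to its (total carbons,
    total double bonds); pass a callable taking the transition.
    """
    class_intercepts = class_intercepts or {}
    rows = []
    for t in transitions:
        c, d = species_lookup(t)
        rt = class_intercepts.get(t.lipid_class, base_intercept) + (
            per_carbon * c - per_double_bond * d
        )
        rows.append(
            {
                "transition_id": t.transition_id,
                "mz": t.q1,
                "rt": rt,
                "lipid_class": t.lipid_class,
                "total_carbons": c,
                "total_double_bonds": d,
            }
        )
    return pd.DataFrame(rows)
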