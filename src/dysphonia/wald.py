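"""Decision-theoretic classification of affected phonatory dimensions.

The 15 acoustic measures group into 7 clinically interpretable phonatory
dimensions (airflow insufficiency, aperiodicity, irregular vibration,
signal perturbation, increased noise, vocal tremor, articulation
deficiency).  For each measure, class-conditional Gaussians are fitted to
the control and patient groups; a subject's measure votes "pathological"
when the likelihood ratio favours the patient distribution *and* the value
lies on the pathological side of the control mean (the one-sided guard
prevents flagging exceptionally good voices).  A dimension is affected when
at least one of its measures votes pathological.  With equal priors this is
the minimum-error (Wald) two-hypothesis decision rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DIMENSIONS",
    "MEASURES",
    "DimensionModel",
    "PhonatoryProfile",
    "fit_dimension_model",
    "classify_subject",
    "classify_table",
    "affected_summary",
    "plot_affected_summary",
]

#: The 7 phonatory dimensions and their measures (15 in total).
DIMENSIONS: dict[str, tuple[str, ...]] = {
    "airflow_insufficiency": ("MPT", "FOVB"),
    "aperiodicity": ("NVB", "DPB", "DVA"),
    "irregular_vibration": ("F0_SD", "RPDE"),
    "signal_perturbation": ("Jitter", "Shimmer"),
    "increased_noise": ("HNR", "DFA"),
    "vocal_tremor": ("FTRI", "ATRI"),
    "articulation_deficiency": ("MFCC", "dMFCC"),
}

MEASURES: tuple[str, ...] = tuple(m for ms in DIMENSIONS.values() for m in ms)


@dataclass
class _Gaussians:
    control_mean: float
    control_sd: float
    patient_mean: float
    patient_sd: float
    orientation: int  # +1: high is pathological; -1: low; 0: undefined


@dataclass
class DimensionModel:
    """Fitted class-conditional Gaussians per measure."""

    per_measure: dict[str, _Gaussians]
    dim_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DIMENSIONS)
    )

    def usable_measures(self) -> list[str]:
        return [m for m, g in self.per_measure.items() if g.orientation != 0]


@dataclass
class PhonatoryProfile:
    """Affected/unaffected flags for one subject."""

    subject: str
    affected: dict[str, bool]

    @property
    def n_affected(self) -> int:
        return sum(self.affected.values())


def fit_dimension_model(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    control_label: str = "control",
    dim_map: dict[str, tuple[str, ...]] | None = None,
) -> DimensionModel:
    """Fit per-measure control/patient Gaussians.

    ``labels`` holds the group per row; ``control_label`` names the control
    group, every other label is pooled as patient.  SDs are floored so a
    constant measure (e.g. a zero arrest rate among controls) cannot cause
    a division error; measures whose groups have identical means carry no
    orientation and are excluded from decisions.
    """
    if dim_map is None:
        dim_map = dict(DIMENSIONS)
    labels = np.asarray(labels)
    is_control = labels == control_label
    if is_control.sum() < 3 or (~is_control).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    measures = [m for ms in dim_map.values() for m in ms]
    per_measure: dict[str, _Gaussians] = {}
    for m in measures:
        if m not in table.columns:
            continue
        x = pd.to_numeric(table[m], errors="coerce").to_numpy(dtype=float)
        xc = x[is_control & np.isfinite(x)]
        xp = x[~is_control & np.isfinite(x)]
        if xc.size < 3 or xp.size < 3:
            continue
        mc, mp = float(xc.mean()), float(xp.mean())
        pooled_range = float(np.ptp(np.concatenate([xc, xp])))
        floor = max(1e-6 * max(pooled_range, 1.0), 1e-12)
        sc = max(float(xc.std(ddof=1)), floor)
        sp = max(float(xp.std(ddof=1)), floor)
        diff = mp - mc
        orientation = 0 if diff == 0 else (1 if diff > 0 else -1)
        if orientation == 0:
            logger.warning("measure %s has identical group means; excluded", m)
        per_measure[m] = _Gaussians(mc, sc, mp, sp, orientation)
    if not per_measure:
        raise ValueError("no usable measures to fit")
    return DimensionModel(per_measure, dim_map)


def _log_norm_pdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd)


def classify_subject(
    model: DimensionModel, features: dict | pd.Series, subject: str = ""
) -> PhonatoryProfile:
    """Decide which phonatory dimensions are affected for one subject.

    A missing or non-finite measure abstains (logged at debug level).
    """
    affected = {}
    for dim, measures in model.dim_map.items():
        votes = []
        for m in measures:
            g = model.per_measure.get(m)
            if g is None or g.orientation == 0:
                continue
            x = features.get(m) if isinstance(features, dict) else features.get(m, np.nan)
            if x is None or not np.isfinite(x):
                logger.debug("subject %s: measure %s missing, abstains", subject, m)
                continue
            x = float(x)
            llr = _log_norm_pdf(x, g.patient_mean, g.patient_sd) - _log_norm_pdf(
                x, g.control_mean, g.control_sd
            )
            pathological_side = g.orientation * (x - g.control_mean) > 0
            votes.append(llr > 0 and pathological_side)
        affected[dim] = any(votes)
    return PhonatoryProfile(subject=subject, affected=affected)


def classify_table(
    model: DimensionModel, table: pd.DataFrame, subject_col: str = "subject"
) -> list[PhonatoryProfile]:
    """Classify every row of a feature table."""
    profiles = []
    for _, row in table.iterrows():
        sid = str(row[subject_col]) if subject_col in row else str(_)
        profiles.append(classify_subject(model, row, subject=sid))
    return profiles


def affected_summary(
    profiles: list[PhonatoryProfile], labels: dict | pd.Series | None = None
) -> dict:
    """Per-dimension affected percentages and the affected-count histogram.

    ``labels`` maps subject id -> group; without it all profiles form one
    group.  Returns ``{"percent_affected": DataFrame(dimension x group),
    "n_affected_hist": DataFrame(count x group), "profiles": DataFrame}``.
    """
    if not profiles:
        raise ValueError("no profiles to summarise")
    rows = []
    for p in profiles:
        group = "all"
        if labels is not None:
            group = labels.get(p.subject, "all") if hasattr(labels, "get") else "all"
        row = {"subject": p.subject, "group": group, "n_affected": p.n_affected}
        row.update({d: bool(v) for d, v in p.affected.items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    dims = list(profiles[0].affected)
    pct = df.groupby("group")[dims].mean().T * 100.0
    max_n = len(dims)
    hist = (
        df.groupby("group")["n_affected"]
        .value_counts()
        .unstack(0, fill_value=0)
        .reindex(range(max_n + 1), fill_value=0)
    )
    return {"percent_affected": pct, "n_affected_hist": hist, "profiles": df}


def plot_affected_summary(summary: dict, path: str) -> None:
    """Bar chart of per-dimension affected percentages per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = summary["percent_affected"]
    ax = pct.plot.bar(figsize=(8, 4))
    ax.set_ylabel("affected participants (%)")
    ax.set_ylim(0, 100)
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()
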