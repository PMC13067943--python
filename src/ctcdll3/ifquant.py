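"""Per-event gating of CTC-enriched immunofluorescence feature tables.

Events (segmented cells/fragments from whole-slide imaging of a
leukocyte-depleted blood product) are classified into CTC classes,
leukocytes and tumor fragments from exposure-normalized channel intensities,
then enumerated per patient with counts scaled to a reference blood volume.

A CTC is a hematopoietic-marker-negative, nucleated, intact event positive
for the epithelial cocktail and/or DLL3.  DLL3 positivity requires the
normalized cytoplasmic intensity to strictly exceed the threshold (default
20 on the 8-bit scale).  Gating uses the cytoplasmic-mask mean for the
membrane/cytoplasmic markers and the nuclear-mask mean for the nuclear
stain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

CHANNELS = ("dapi", "epi", "dll3", "cd45")

#: event labels; the six labels partition every input table
LABELS = ("CTC_DLL3_only", "CTC_epithelial_only", "CTC_dual",
          "leukocyte", "fragment", "negative")
CTC_LABELS = ("CTC_DLL3_only", "CTC_epithelial_only", "CTC_dual")

#: feature columns the gating stage requires
REQUIRED_COLUMNS = tuple(
    [f"{ch}_{comp}" for ch in CHANNELS for comp in ("nuc", "cyt")]
    + [f"exposure_{ch}" for ch in CHANNELS] + ["area_um2"]
)


@dataclass(frozen=True)
class GatingConfig:
    """Gating thresholds on exposure-normalized 8-bit intensities.

    ``dll3_threshold`` is the published positivity cutoff (strictly
    exceeded).  The epithelial, hematopoietic-exclusion and nucleation
    thresholds are not published; the defaults are calibrated on synthetic
    positive/negative control populations (see :func:`calibrate_threshold`)
    the way the assay calibrates on control cell lines and leukocytes.
    """

    dll3_threshold: float = 20.0
    epithelial_threshold: float = 20.0
    hematopoietic_threshold: float = 40.0
    nucleation_threshold: float = 15.0
    min_area_um2: float = 30.0
    reference_volume_ml: float = 20.0

    def __post_init__(self) -> None:
        for name in ("dll3_threshold", "epithelial_threshold",
                     "hematopoietic_threshold", "nucleation_threshold",
                     "min_area_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reference_volume_ml <= 0:
            raise ValueError("reference_volume_ml must be > 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GatingConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown GatingConfig keys: {sorted(unknown)}")
        return cls(**d)

    def with_(self, **kw) -> "GatingConfig":
        return replace(self, **kw)


def calibrate_threshold(negative: np.ndarray, positive: np.ndarray,
                        q: float = 0.999) -> float:
    """Threshold between control populations: midpoint of the negative
    population's upper ``q`` quantile and the positive population's lower
    ``1 - q`` quantile.  Raises if the controls are not separable."""
    neg_hi = float(np.quantile(negative, q))
    pos_lo = float(np.quantile(positive, 1.0 - q))
    if pos_lo <= neg_hi:
        raise ValueError("control populations are not separable at this quantile")
    return 0.5 * (neg_hi + pos_lo)


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")


def normalize_intensities(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each channel's nuclear and cytoplasmic intensity by that
    channel's exposure factor (actual / reference exposure).

    Returns a new table with exposure factors reset to 1, so normalization
    is idempotent.  Nonpositive exposure factors raise.
    """
    _check_columns(records)
    out = records.copy()
    for ch in CHANNELS:
        fac = out[f"exposure_{ch}"].to_numpy(float)
        if (fac <= 0).any():
            raise ValueError(f"nonpositive exposure factor in channel {ch!r}")
        out[f"{ch}_nuc"] = out[f"{ch}_nuc"].to_numpy(float) / fac
        out[f"{ch}_cyt"] = out[f"{ch}_cyt"].to_numpy(float) / fac
        out[f"exposure_{ch}"] = 1.0
    return out


def classify_events(records: pd.DataFrame, config: GatingConfig | None = None,
                    *, normalized: bool = False) -> pd.DataFrame:
    """Gate every event into exactly one of the six labels.

    Decision order: (1) hematopoietic signal above the exclusion threshold ->
    leukocyte; (2) non-nucleated or sub-minimum-area event with any tumor
    marker positive -> fragment; (3) otherwise by marker combination
    (epithelial and/or DLL3), else negative.  All gates are strict ``>``.

    Returns the input columns plus ``label`` and ``dll3_positive`` (true iff
    the normalized DLL3 intensity strictly exceeds the threshold, regardless
    of label), with intensities replaced by their normalized values.
    """
    config = config or GatingConfig()
    df = records if normalized else normalize_intensities(records)
    for col in ("dll3_cyt", "epi_cyt", "cd45_cyt", "dapi_nuc", "area_um2"):
        if df[col].isna().any():
            raise ValueError(f"missing value in channel/feature {col!r}")

    dll3 = df["dll3_cyt"].to_numpy(float) > config.dll3_threshold
    epi = df["epi_cyt"].to_numpy(float) > config.epithelial_threshold
    hem = df["cd45_cyt"].to_numpy(float) > config.hematopoietic_threshold
    broken = ((df["dapi_nuc"].to_numpy(float) < config.nucleation_threshold)
              | (df["area_um2"].to_numpy(float) < config.min_area_um2))

    label = np.select(
        [hem,
         broken & (dll3 | epi),
         epi & dll3,
         epi,
         dll3],
        ["leukocyte", "fragment", "CTC_dual", "CTC_epithelial_only",
         "CTC_DLL3_only"],
        default="negative",
    )
    out = df.copy()
    out["label"] = pd.Categorical(label, categories=list(LABELS))
    out["dll3_positive"] = dll3
    return out


def enumerate_ctcs(calls: pd.DataFrame, blood_volume_ml: float | None = None,
                   config: GatingConfig | None = None,
                   by: tuple[str, ...] = ("patient_id",)) -> pd.DataFrame:
    """Per-group event counts with CTC totals scaled to the reference volume.

    ``blood_volume_ml`` may be a scalar or, when None, taken from the calls'
    ``volume_ml`` column (must be constant within a group).  Scaled counts
    are raw counts x (reference volume / actual volume); raw counts stay
    integral, scaled counts are real.
    """
    config = config or GatingConfig()
    rows = []
    for key, grp in calls.groupby(list(by), observed=True, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if blood_volume_ml is None:
            vols = grp["volume_ml"].unique()
            if len(vols) != 1:
                raise ValueError(f"non-constant blood volume in group {key}")
            vol = float(vols[0])
        else:
            vol = float(blood_volume_ml)
        if vol <= 0:
            raise ValueError("blood volume must be > 0")
        scale = config.reference_volume_ml / vol
        counts = grp["label"].value_counts()
        row = dict(zip(by, key))
        for lab in LABELS:
            row[f"n_{lab}"] = int(counts.get(lab, 0))
        total = sum(row[f"n_{lab}"] for lab in CTC_LABELS)
        pos = row["n_CTC_DLL3_only"] + row["n_CTC_dual"]
        row.update({
            "n_events": int(len(grp)),
            "volume_ml": vol,
            "total_ctc": total,
            "dll3_pos_ctc": pos,
            "total_ctc_per_ref": total * scale,
            "dll3_pos_ctc_per_ref": pos * scale,
            "fragments_per_ref": row["n_fragment"] * scale,
            "dll3_fraction_pct": 100.0 * pos / total if total else np.nan,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def size_summary(calls: pd.DataFrame, bins: np.ndarray | None = None,
                 by: str = "label") -> pd.DataFrame:
    """Per-class cell-area summaries: n, mean, median and a histogram as the
    percentage of the class's cells per bin (um^2).  Empty classes yield a
    flagged empty row rather than an error."""
    if bins is None:
        bins = np.arange(0.0, 310.0, 10.0)
    rows = []
    groups = calls[by].cat.categories if isinstance(calls[by].dtype, pd.CategoricalDtype) \
        else sorted(calls[by].unique())
    for cls in groups:
        area = calls.loc[calls[by] == cls, "area_um2"].to_numpy(float)
        if area.size == 0:
            rows.append({by: cls, "n": 0, "mean": np.nan, "median": np.nan,
                         "empty": True})
            continue
        hist, _ = np.histogram(area, bins=bins)
        row = {by: cls, "n": int(area.size), "mean": float(area.mean()),
               "median": float(np.median(area)), "empty": False}
        for lo, pct in zip(bins[:-1], 100.0 * hist / area.size):
            row[f"pct_{lo:g}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
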