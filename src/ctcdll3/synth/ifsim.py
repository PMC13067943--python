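"""Synthetic per-cell immunofluorescence feature tables.

Emulates the per-event feature matrix exported after whole-slide imaging of a
leukocyte-depleted, CTC-enriched blood product: one row per segmented imaging
event with mean nuclear/cytoplasmic intensity per channel on the 8-bit scale,
cell area, per-channel exposure factors and identity metadata.  Event classes
(DLL3-only / epithelial-only / dual CTCs, carryover leukocytes, anucleate
tumor fragments, rare marker-positive background events) are drawn with known
per-patient ground truth so downstream gating is testable end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: imaging channels: nuclear stain, epithelial cocktail (EpCAM/pan-CK/CK19),
#: DLL3, hematopoietic cocktail (CD45/CD66b/CD16)
CHANNELS = ("dapi", "epi", "dll3", "cd45")

#: ground-truth event classes
EVENT_CLASSES = (
    "ctc_dll3", "ctc_epithelial", "ctc_dual", "leukocyte", "fragment",
    "background",
)

# Class-conditional intensity model on the 8-bit scale: (mean, sd) of the
# primary-compartment mean intensity per channel.  Calibrated on synthetic
# positive/negative control populations so that positive classes sit well
# above the gating thresholds and negative classes well below (the assay
# calibrates the same way on control cell lines and leukocytes).
DEFAULT_INTENSITY_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "ctc_dll3":       {"dapi": (150, 30), "epi": (4, 3),    "dll3": (120, 25), "cd45": (4, 3)},
    "ctc_epithelial": {"dapi": (150, 30), "epi": (120, 25), "dll3": (4, 3),    "cd45": (4, 3)},
    "ctc_dual":       {"dapi": (150, 30), "epi": (120, 25), "dll3": (120, 25), "cd45": (4, 3)},
    "leukocyte":      {"dapi": (150, 30), "epi": (4, 3),    "dll3": (4, 3),    "cd45": (160, 30)},
    "fragment":       {"dapi": (3, 2),    "epi": (4, 3),    "dll3": (4, 3),    "cd45": (4, 3)},
    "background":     {"dapi": (150, 30), "epi": (90, 25),  "dll3": (4, 3),    "cd45": (4, 3)},
}

#: mean cell areas in um^2 (leukocyte 61, intact CTC 77.7, fragments small)
DEFAULT_AREA_MODEL: dict[str, tuple[float, float]] = {
    "ctc_dll3": (77.7, 15.0),
    "ctc_epithelial": (77.7, 15.0),
    "ctc_dual": (77.7, 15.0),
    "leukocyte": (61.0, 10.0),
    "fragment": (15.0, 5.0),
    "background": (77.7, 15.0),
}


@dataclass(frozen=True)
class IFCohortParams:
    """Parameters of a synthetic IF cohort.

    ``dll3_fraction`` and ``ctc_abundance`` may be scalars (shared) or one
    value per patient.  ``ctc_abundance`` is the expected CTC count per 20 mL
    of blood; the realized event count scales with ``blood_volume_ml``.
    ``timepoints`` is a sequence of ``(label, on_treatment)`` pairs; fragment
    bursts are injected only at on-treatment draws.
    """

    n_patients: int
    dll3_fraction: float | Sequence[float] = 0.5
    ctc_abundance: float | Sequence[float] = 300.0
    leukocyte_carryover: float = 200.0
    fragment_burst_size: float = 10_000.0
    background_rate: float = 0.18          # marker-positive events per mL
    dual_positive_prob: float = 0.16       # DLL3+ CTC also epithelial+
    blood_volume_ml: float = 20.0
    timepoints: Sequence[tuple[str, bool]] = (("baseline", False),)
    intensity_model: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_INTENSITY_MODEL)
    area_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_AREA_MODEL)
    exposure_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for frac in np.atleast_1d(np.asarray(self.dll3_fraction, float)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"dll3_fraction must be in [0, 1], got {frac}")
        if not 0.0 <= self.dual_positive_prob <= 1.0:
            raise ValueError("dual_positive_prob must be in [0, 1]")
        for name in ("ctc_abundance", "leukocyte_carryover",
                     "fragment_burst_size", "background_rate"):
            val = np.atleast_1d(np.asarray(getattr(self, name), float))
            if (val < 0).any():
                raise ValueError(f"{name} must be nonnegative")
        if self.blood_volume_ml <= 0:
            raise ValueError("blood_volume_ml must be positive")
        lo, hi = self.exposure_range
        if lo <= 0 or hi < lo:
            raise ValueError("exposure_range must be positive with lo <= hi")
        for cls, model in self.intensity_model.items():
            for ch, (mu, _sd) in model.items():
                if not 0 <= mu <= 255:
                    raise ValueError(
                        f"intensity mean for {cls}/{ch} must be in [0, 255]")

    def per_patient(self, name: str) -> np.ndarray:
        val = np.asarray(getattr(self, name), float)
        if val.ndim == 0:
            return np.full(self.n_patients, float(val))
        if val.shape != (self.n_patients,):
            raise ValueError(f"{name} must be scalar or length n_patients")
        return val


def _draw_intensities(rng: np.random.Generator, classes: np.ndarray,
                      model: Mapping, out: dict[str, np.ndarray]) -> None:
    """Fill nuclear/cytoplasmic channel columns, class-conditionally.

    The primary compartment (nuclear for the nuclear stain, cytoplasmic for
    the marker channels) is drawn from the class model and clipped to the
    8-bit range; the secondary compartment is a damped copy with noise.
    """
    for cls in np.unique(classes):
        idx = np.flatnonzero(classes == cls)
        for ch in CHANNELS:
            mu, sd = model[cls][ch]
            prim = np.clip(rng.normal(mu, sd, idx.size), 0.0, 255.0)
            sec = np.clip(prim * (0.3 if ch == "dapi" else 0.5)
                          + rng.normal(0, 2, idx.size), 0.0, 255.0)
            if ch == "dapi":
                out[f"{ch}_nuc"][idx], out[f"{ch}_cyt"][idx] = prim, sec
            else:
                out[f"{ch}_cyt"][idx], out[f"{ch}_nuc"][idx] = prim, sec


def simulate_if_cohort(params: IFCohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of per-event IF feature tables.

    Returns ``(events, truth)``: one row per imaging event with the feature
    columns the gating stage consumes, and the matching ground-truth class
    per event id.  Identical params (including seed) give identical tables.
    """
    rng = np.random.default_rng(params.seed)
    fracs = params.per_patient("dll3_fraction")
    rates = params.per_patient("ctc_abundance")
    vol = params.blood_volume_ml

    pat_ids, tp_ids, classes = [], [], []
    for p in range(params.n_patients):
        pid = f"P{p + 1:02d}"
        for label, on_treatment in params.timepoints:
            n_ctc = rng.poisson(rates[p] * vol / 20.0)
            pos = rng.random(n_ctc) < fracs[p]
            dual = pos & (rng.random(n_ctc) < params.dual_positive_prob)
            cls = np.where(dual, "ctc_dual",
                           np.where(pos, "ctc_dll3", "ctc_epithelial"))
            n_leuk = rng.poisson(params.leukocyte_carryover)
            n_frag = rng.poisson(params.fragment_burst_size) if on_treatment else 0
            n_bg = rng.poisson(params.background_rate * vol)
            block = np.concatenate([
                cls,
                np.repeat("leukocyte", n_leuk),
                np.repeat("fragment", n_frag),
                np.repeat("background", n_bg),
            ])
            classes.append(block)
            pat_ids += [pid] * block.size
            tp_ids += [label] * block.size

    classes = np.concatenate(classes) if classes else np.empty(0, dtype="U16")
    n = classes.size
    cols: dict[str, np.ndarray] = {
        f"{ch}_{comp}": np.zeros(n) for ch in CHANNELS for comp in ("nuc", "cyt")
    }
    _draw_intensities(rng, classes, params.intensity_model, cols)

    # fragments carry tumor-marker signal without a nucleus: reassign their
    # epithelial / DLL3 channels from the CTC-class models
    frag = np.flatnonzero(classes == "fragment")
    if frag.size:
        kind = rng.choice(3, frag.size, p=[0.4, 0.4, 0.2])  # epi / dll3 / dual
        for k, chans in enumerate((("epi",), ("dll3",), ("epi", "dll3"))):
            sub = frag[kind == k]
            for ch in chans:
                mu, sd = params.intensity_model["ctc_dual"][ch]
                prim = np.clip(rng.normal(mu, sd, sub.size), 0.0, 255.0)
                cols[f"{ch}_cyt"][sub] = prim
                cols[f"{ch}_nuc"][sub] = np.clip(
                    prim * 0.5 + rng.normal(0, 2, sub.size), 0.0, 255.0)

    area = np.zeros(n)
    for cls in np.unique(classes):
        mu, sd = params.area_model[cls]
        idx = classes == cls
        area[idx] = np.maximum(rng.normal(mu, sd, int(idx.sum())), 1.0)

    events = pd.DataFrame({
        "event_id": [f"E{i:07d}" for i in range(n)],
        "patient_id": pat_ids,
        "timepoint": tp_ids,
        **cols,
        "area_um2": area,
        "volume_ml": vol,
    })
    # per-slide (patient x timepoint x channel) exposure factors; recorded
    # intensities scale with exposure and are divided back out in scoring
    lo, hi = params.exposure_range
    for ch in CHANNELS:
        factors = {key: rng.uniform(lo, hi)
                   for key in events.groupby(["patient_id", "timepoint"]).groups}
        fac = events.set_index(["patient_id", "timepoint"]).index.map(factors)
        fac = np.asarray(fac, float)
        events[f"{ch}_nuc"] = np.clip(events[f"{ch}_nuc"] * fac, 0.0, 255.0)
        events[f"{ch}_cyt"] = np.clip(events[f"{ch}_cyt"] * fac, 0.0, 255.0)
        events[f"exposure_{ch}"] = fac

    truth = pd.DataFrame({
        "event_id": events["event_id"],
        "patient_id": events["patient_id"],
        "timepoint": events["timepoint"],
        "true_class": classes,
    })
    return events, truth


def true_fractions(params: IFCohortParams) -> pd.Series:
    """The generative per-patient DLL3-positive CTC fraction (as set)."""
    fracs = params.per_patient("dll3_fraction")
    return pd.Series(fracs, index=[f"P{p + 1:02d}" for p in range(params.n_patients)],
                     name="dll3_fraction")


def params_to_dict(params: IFCohortParams) -> dict:
    """JSON/YAML-serializable view of the parameters (seed included)."""
    d = dataclasses.asdict(params)
    d["timepoints"] = [list(t) for t in params.timepoints]
    return d
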