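"""Nine-group NTH dyslipidemia phenotyping.

A subject is *normolipidemic* when all three raw panel values — non-HDL
cholesterol, triglycerides and HDL cholesterol — fall inside their
population interquartile windows (endpoints inclusive). Otherwise the
subject receives a three-letter label: one letter per axis (N/n for
non-HDLC, T/t for triglycerides, H/h for 1/HDLC), upper-case when the
value exceeds the population median and lower-case at or below it. The
H axis is evaluated on the *inverse* of HDL cholesterol so that a capital
letter always means "worse": capital H is low HDLC.

Default cutoffs are the US-population (NHANES-derived) reference values;
:func:`calibrate_cutoffs` recomputes them for any cohort, since reference
windows do not transfer across populations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateDistributionError, DomainError
from .lipid_model import CohortTable, LipidPanel

logger = logging.getLogger(__name__)

#: The nine phenotype labels in canonical display order.
PHENOTYPE_LABELS = (
    "normolipidemic",
    "nth",
    "ntH",
    "nTh",
    "nTH",
    "Nth",
    "NtH",
    "NTh",
    "NTH",
)


@dataclass(frozen=True)
class PhenotypeCutoffs:
    """Normolipidemia windows (raw scale) and letter-assignment medians.

    Windows are closed intervals on the raw values (mg/dL); the letter
    medians apply to non-HDLC and TG on the raw scale and to the H axis on
    the inverse-HDLC scale (dL/mg). Defaults are the US reference values:
    windows 120-175 / 75-160 / 40-60 mg/dL, rounded medians 150 / 110 /
    0.02.
    """

    normo_nhdlc: tuple[float, float] = (120.0, 175.0)
    normo_tg: tuple[float, float] = (75.0, 160.0)
    normo_hdlc: tuple[float, float] = (40.0, 60.0)
    median_nhdlc: float = 150.0
    median_tg: float = 110.0
    median_inv_h: float = 0.02

    def __post_init__(self) -> None:
        for name in ("normo_nhdlc", "normo_tg", "normo_hdlc"):
            low, high = getattr(self, name)
            if not low < high:
                raise DomainError(f"{name}: window low ({low}) must be < high ({high})")
        for name in ("median_nhdlc", "median_tg", "median_inv_h"):
            m = getattr(self, name)
            if not (math.isfinite(m) and m > 0):
                raise DomainError(f"{name} must be finite and positive, got {m}")


#: US-population default cutoffs.
DEFAULT_CUTOFFS = PhenotypeCutoffs()


def classify_values(
    nhdlc: float, tg: float, hdlc: float, cutoffs: PhenotypeCutoffs = DEFAULT_CUTOFFS
) -> str:
    """Classify one (nhdlc, tg, hdlc) triple into one of the 9 phenotypes."""
    if (
        cutoffs.normo_nhdlc[0] <= nhdlc <= cutoffs.normo_nhdlc[1]
        and cutoffs.normo_tg[0] <= tg <= cutoffs.normo_tg[1]
        and cutoffs.normo_hdlc[0] <= hdlc <= cutoffs.normo_hdlc[1]
    ):
        return "normolipidemic"
    n = "N" if nhdlc > cutoffs.median_nhdlc else "n"
    t = "T" if tg > cutoffs.median_tg else "t"
    h = "H" if (1.0 / hdlc) > cutoffs.median_inv_h else "h"
    return n + t + h


def classify_phenotype(
    panel: LipidPanel, cutoffs: PhenotypeCutoffs = DEFAULT_CUTOFFS
) -> str:
    """Assign the NTH phenotype label to one subject."""
    return classify_values(panel.nhdlc, panel.tg, panel.hdlc, cutoffs)


def classify_batch(
    nhdlc: np.ndarray,
    tg: np.ndarray,
    hdlc: np.ndarray,
    cutoffs: PhenotypeCutoffs = DEFAULT_CUTOFFS,
) -> np.ndarray:
    """Vectorised classification; returns an array of label strings."""
    nhdlc = np.asarray(nhdlc, dtype=float)
    tg = np.asarray(tg, dtype=float)
    hdlc = np.asarray(hdlc, dtype=float)
    normo = (
        (cutoffs.normo_nhdlc[0] <= nhdlc)
        & (nhdlc <= cutoffs.normo_nhdlc[1])
        & (cutoffs.normo_tg[0] <= tg)
        & (tg <= cutoffs.normo_tg[1])
        & (cutoffs.normo_hdlc[0] <= hdlc)
        & (hdlc <= cutoffs.normo_hdlc[1])
    )
    letters = np.where(nhdlc > cutoffs.median_nhdlc, "N", "n")
    letters = np.char.add(letters, np.where(tg > cutoffs.median_tg, "T", "t"))
    letters = np.char.add(
        letters, np.where(1.0 / hdlc > cutoffs.median_inv_h, "H", "h")
    )
    return np.where(normo, "normolipidemic", letters)


def _round_to(value: float, increment: float | None) -> float:
    if increment is None:
        return value
    # round half away from zero so e.g. 145 -> 150 at increment 10
    return math.floor(value / increment + 0.5) * increment


def calibrate_cutoffs(
    cohort: CohortTable,
    rounding: Mapping[str, float] | None = None,
) -> PhenotypeCutoffs:
    """Derive population cutoffs from a cohort.

    Windows are the [25th, 75th] percentiles of nhdlc, tg and hdlc; letter
    medians are the 50th percentiles of nhdlc, tg and inv_h. ``rounding``
    optionally maps feature names (``nhdlc``, ``tg``, ``hdlc``, ``inv_h``)
    to rounding increments applied to that feature's window bounds and
    median (half rounded away from zero). The US reference values
    correspond to increments of 10 mg/dL (146 -> 150, 107 -> 110) and
    0.005 dL/mg for the inverse-HDLC median; rounding is off by default.
    """
    if len(cohort) < 2:
        raise DomainError("calibration requires at least 2 records")
    rounding = dict(rounding or {})
    arr = cohort.feature_array(["nhdlc", "tg", "hdlc", "inv_h"])
    for j, name in enumerate(("nhdlc", "tg", "hdlc", "inv_h")):
        if np.unique(arr[:, j]).size < 2:
            raise DegenerateDistributionError(
                f"feature {name!r} is constant; cannot calibrate cutoffs"
            )
    q = {
        name: np.percentile(arr[:, j], [25.0, 50.0, 75.0])
        for j, name in enumerate(("nhdlc", "tg", "hdlc", "inv_h"))
    }

    def window(name: str) -> tuple[float, float]:
        inc = rounding.get(name)
        return (_round_to(q[name][0], inc), _round_to(q[name][2], inc))

    return PhenotypeCutoffs(
        normo_nhdlc=window("nhdlc"),
        normo_tg=window("tg"),
        normo_hdlc=window("hdlc"),
        median_nhdlc=_round_to(q["nhdlc"][1], rounding.get("nhdlc")),
        median_tg=_round_to(q["tg"][1], rounding.get("tg")),
        median_inv_h=_round_to(q["inv_h"][1], rounding.get("inv_h")),
    )


def tabulate_distribution(
    cohort: CohortTable, cutoffs: PhenotypeCutoffs = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """Phenotype counts and percentages for a cohort.

    Returns a DataFrame indexed by the nine labels (canonical order) with
    ``count`` and ``percent`` columns; counts partition the cohort.
    """
    if len(cohort) == 0:
        raise DomainError("cannot tabulate an empty cohort")
    arr = cohort.feature_array(["nhdlc", "tg", "hdlc"])
    labels = classify_batch(arr[:, 0], arr[:, 1], arr[:, 2], cutoffs)
    counts = pd.Series(labels).value_counts()
    out = pd.DataFrame(
        {
            "count": [int(counts.get(lbl, 0)) for lbl in PHENOTYPE_LABELS],
            "percent": [
                100.0 * counts.get(lbl, 0) / len(cohort) for lbl in PHENOTYPE_LABELS
            ],
        },
        index=pd.Index(PHENOTYPE_LABELS, name="phenotype"),
    )
    return out


def cutoffs_to_file(cutoffs: PhenotypeCutoffs, path: str) -> None:
    """Serialise cutoffs as a flat key = value text file."""
    lines = [
        f"normo_nhdlc_low = {cutoffs.normo_nhdlc[0]!r}",
        f"normo_nhdlc_high = {cutoffs.normo_nhdlc[1]!r}",
        f"normo_tg_low = {cutoffs.normo_tg[0]!r}",
        f"normo_tg_high = {cutoffs.normo_tg[1]!r}",
        f"normo_hdlc_low = {cutoffs.normo_hdlc[0]!r}",
        f"normo_hdlc_high = {cutoffs.normo_hdlc[1]!r}",
        f"median_nhdlc = {cutoffs.median_nhdlc!r}",
        f"median_tg = {cutoffs.median_tg!r}",
        f"median_inv_h = {cutoffs.median_inv_h!r}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def cutoffs_from_file(path: str) -> PhenotypeCutoffs:
    """Read cutoffs written by :func:`cutoffs_to_file`."""
    kv: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = float(value.strip())
    try:
        return PhenotypeCutoffs(
            normo_nhdlc=(kv["normo_nhdlc_low"], kv["normo_nhdlc_high"]),
            normo_tg=(kv["normo_tg_low"], kv["normo_tg_high"]),
            normo_hdlc=(kv["normo_hdlc_low"], kv["normo_hdlc_high"]),
            median_nhdlc=kv["median_nhdlc"],
            median_tg=kv["median_tg"],
            median_inv_h=kv["median_inv_h"],
        )
    except KeyError as exc:
        raise DomainError(f"cutoffs file {path} missing key {exc}") from None
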