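"""Variable-slope Hill fitting of concentration–response data.

Each oocyte recording is a set of peak currents measured at increasing
agonist concentrations.  The response model is the variable-slope sigmoid

    I(c) = Imax * c**h / (c**h + EC50**h)

fit by unweighted nonlinear least squares in linear response space, with
EC50 and the Hill slope h optimised on a log scale.  Per-oocyte fits are
then averaged (mean ± sample SD) into per-construct summaries, mirroring
standard TEVC practice where every oocyte contributes one EC50 and one
Hill coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ConcentrationResponse",
    "HillFit",
    "ConstructSummary",
    "FoldChange",
    "NoResponseError",
    "hill_current",
    "fit_hill",
    "summarize_construct",
    "fold_change",
    "fold_from_ratio",
    "read_responses_csv",
    "write_responses_csv",
    "read_summary_csv",
    "summaries_to_frame",
]

#: Construct status codes: functional, no response, no expression,
#: expressed but non-functional.
FUNCTIONAL = "functional"
NO_RESPONSE = "NR"
NO_EXPRESSION = "NE"
NON_FUNCTIONAL = "NF"

_HILL_BOUNDS = (0.2, 10.0)


class NoResponseError(ValueError):
    """Raised when a recording carries no agonist-induced current."""


@dataclass(frozen=True)
class ConcentrationResponse:
    """One oocyte's concentration–response series for one construct.

    Parameters
    ----------
    construct : str
        Construct label, e.g. ``"WT"`` or ``"aE45R"``.
    oocyte_id : str
        Identifier of the individual oocyte (one fit per oocyte).
    concentrations : array-like
        Agonist concentrations in µM, strictly positive.
    currents : array-like
        Peak current amplitudes (normalised units), non-negative.
    """

    construct: str
    oocyte_id: str
    concentrations: np.ndarray
    currents: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        curr = np.asarray(self.currents, dtype=float)
        if conc.shape != curr.shape or conc.ndim != 1:
            raise ValueError("concentrations and currents must be paired 1-D vectors")
        bad = conc[conc <= 0]
        if bad.size:
            raise ValueError(f"non-positive concentration not allowed: {bad[0]!r} µM")
        if np.any(curr < 0):
            raise ValueError("currents must be non-negative")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "currents", curr)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters for a single recording."""

    ec50: float
    hill: float
    imax: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class ConstructSummary:
    """Per-construct aggregate: mean ± sample SD over per-oocyte fits.

    Non-functional constructs (status ``NR``/``NE``/``NF``) carry no
    numeric estimates (all-NaN fields, ``n = 0``).
    """

    construct: str
    ec50_mean: float = math.nan
    ec50_sd: float = math.nan
    hill_mean: float = math.nan
    hill_sd: float = math.nan
    n: int = 0
    status: str = FUNCTIONAL

    @property
    def is_functional(self) -> bool:
        return self.status == FUNCTIONAL


@dataclass(frozen=True)
class FoldChange:
    """EC50 fold change relative to wild type.

    The magnitude is always >= 1; the direction says whether EC50
    decreased (``gain`` of function) or increased (``loss``).  A ratio
    that rounds to 1.00 at display precision is reported as ``none``.
    """

    magnitude: float
    direction: str  # "gain" | "loss" | "none"

    def __str__(self) -> str:
        disp = round_sig(self.magnitude, 3)
        if self.direction == "none":
            return "1.00"
        return f"{disp:g} {self.direction}"


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def hill_current(
    c: np.ndarray | float, ec50: float, hill: float, imax: float
) -> np.ndarray | float:
    """Variable-slope Hill response ``Imax * c**h / (c**h + EC50**h)``.

    Evaluated in log space for numerical stability on wide grids.
    """
    logc = np.log(np.asarray(c, dtype=float))
    return imax / (1.0 + np.exp(hill * (math.log(ec50) - logc)))


def _initial_ec50(conc: np.ndarray, curr: np.ndarray) -> float:
    """Geometric mean of the concentration pair bracketing half-max."""
    half = curr.max() / 2.0
    above = curr >= half
    if above.all() or not above.any():
        return float(np.exp(np.mean(np.log(conc))))
    # first index where the response crosses half-max
    idx = int(np.argmax(above))
    if idx == 0:
        return float(conc[0])
    return float(math.sqrt(conc[idx - 1] * conc[idx]))


def fit_hill(data: ConcentrationResponse) -> HillFit:
    """Fit the variable-slope Hill model to one recording.

    Least squares in linear response space with parameters
    ``(log EC50, log h, Imax)``; h bounded to (0.2, 10), EC50 bounded to
    the measured concentration bracket times [1e-2, 1e2].

    Raises
    ------
    NoResponseError
        If every current is zero (an ``NF``-type recording: nothing to fit).
    ValueError
        If fewer than 4 distinct concentrations are available.
    """
    conc = data.concentrations
    curr = data.currents
    if np.unique(conc).size < 4:
        raise ValueError("Hill fit requires >= 4 distinct concentrations")
    if not np.any(curr > 0):
        raise NoResponseError(
            f"all currents zero for {data.construct}/{data.oocyte_id}"
        )

    imax0 = float(curr.max())
    ec50_0 = _initial_ec50(conc, curr)
    theta0 = np.array([math.log(ec50_0), math.log(1.5), imax0])
    lo = np.array([math.log(conc.min() * 1e-2), math.log(_HILL_BOUNDS[0]), 1e-12])
    hi = np.array([math.log(conc.max() * 1e2), math.log(_HILL_BOUNDS[1]), np.inf])
    theta0 = np.clip(theta0, lo, hi)
    logc = np.log(conc)

    def resid(theta: np.ndarray) -> np.ndarray:
        log_ec50, log_h, imax = theta
        pred = imax / (1.0 + np.exp(np.exp(log_h) * (log_ec50 - logc)))
        return pred - curr

    res = least_squares(
        resid, theta0, bounds=(lo, hi), xtol=1e-10, ftol=1e-12, gtol=1e-12
    )
    log_ec50, log_h, imax = res.x
    return HillFit(
        ec50=float(math.exp(log_ec50)),
        hill=float(math.exp(log_h)),
        imax=float(imax),
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.status > 0),
    )


def summarize_construct(
    fits: Sequence[HillFit],
    construct: str,
    status_override: str | None = None,
) -> ConstructSummary:
    """Aggregate per-oocyte fits into a construct summary.

    Mean and sample SD (n−1 denominator; SD = 0 for a single fit) are
    computed over converged fits only.  ``status_override`` stamps a
    non-functional status (``NR``/``NE``/``NF``) and skips aggregation.
    """
    if status_override is not None:
        if status_override not in (NO_RESPONSE, NO_EXPRESSION, NON_FUNCTIONAL):
            raise ValueError(f"unknown status override: {status_override!r}")
        return ConstructSummary(construct=construct, status=status_override)
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError(
            f"no converged fits for {construct!r}; pass status_override to record "
            "a non-functional construct"
        )
    ec50s = np.array([f.ec50 for f in good])
    hills = np.array([f.hill for f in good])
    n = len(good)
    sd = lambda v: float(np.std(v, ddof=1)) if n > 1 else 0.0
    return ConstructSummary(
        construct=construct,
        ec50_mean=float(ec50s.mean()),
        ec50_sd=sd(ec50s),
        hill_mean=float(hills.mean()),
        hill_sd=sd(hills),
        n=n,
        status=FUNCTIONAL,
    )


def fold_from_ratio(ratio: float) -> FoldChange:
    """Fold change from the EC50 ratio mutant/WT.

    Ratios >= 1 are losses of function (EC50 increased), ratios < 1 gains
    (reported as the reciprocal so that magnitude >= 1).
    """
    if ratio <= 0 or not math.isfinite(ratio):
        raise ValueError(f"EC50 ratio must be positive and finite, got {ratio!r}")
    magnitude, direction = (ratio, "loss") if ratio >= 1 else (1.0 / ratio, "gain")
    if round_sig(magnitude, 3) == 1.0:
        direction = "none"
    return FoldChange(magnitude=magnitude, direction=direction)


def fold_change(mutant: ConstructSummary, wt: ConstructSummary) -> FoldChange:
    """EC50 fold change of ``mutant`` relative to ``wt``."""
    for s in (mutant, wt):
        if not s.is_functional:
            raise ValueError(
                f"fold change undefined for non-functional construct {s.construct!r} "
                f"(status {s.status})"
            )
    return fold_from_ratio(mutant.ec50_mean / wt.ec50_mean)


# ---------------------------------------------------------------------------
# tidy I/O

_RESPONSE_COLS = ["construct", "oocyte_id", "concentration_uM", "current"]


def write_responses_csv(responses: Iterable[ConcentrationResponse], path) -> None:
    rows = []
    for r in responses:
        for c, i in zip(r.concentrations, r.currents):
            rows.append((r.construct, r.oocyte_id, c, i))
    pd.DataFrame(rows, columns=_RESPONSE_COLS).to_csv(path, index=False)


def read_responses_csv(path) -> list[ConcentrationResponse]:
    df = pd.read_csv(path)
    missing = set(_RESPONSE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"response CSV missing columns: {sorted(missing)}")
    out = []
    for (construct, oocyte), grp in df.groupby(["construct", "oocyte_id"], sort=False):
        out.append(
            ConcentrationResponse(
                construct=str(construct),
                oocyte_id=str(oocyte),
                concentrations=grp["concentration_uM"].to_numpy(float),
                currents=grp["current"].to_numpy(float),
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[ConstructSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct": s.construct,
                "ec50_mean": s.ec50_mean,
                "ec50_sd": s.ec50_sd,
                "hill_mean": s.hill_mean,
                "hill_sd": s.hill_sd,
                "n": s.n,
                "status": s.status,
            }
            for s in summaries
        ]
    )


def read_summary_csv(path) -> list[ConstructSummary]:
    """Read a construct-summary table (e.g. transcribed published values)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        status = str(row.get("status", FUNCTIONAL))
        if status != FUNCTIONAL:
            out.append(ConstructSummary(construct=str(row["construct"]), status=status))
        else:
            out.append(
                ConstructSummary(
                    construct=str(row["construct"]),
                    ec50_mean=float(row["ec50_mean"]),
                    ec50_sd=float(row["ec50_sd"]),
                    hill_mean=float(row["hill_mean"]),
                    hill_sd=float(row["hill_sd"]),
                    n=int(row["n"]),
                )
            )
    return out
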