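"""Mutant-cycle (double and higher-order) coupling analysis on EC50 values.

A mutant cycle asks whether k perturbations act independently.  For two
mutations the interaction factor is

    Omega = EC50(WT) * EC50(mut12) / (EC50(mut1) * EC50(mut2))

and the generalized k-perturbation form used here is

    Omega = EC50(WT)**(k-1) * EC50(combined) / prod_i EC50(mut_i)

which reduces to the two-mutant expression at k = 2.  Omega = 1 means the
combined construct shifts EC50 exactly as predicted by the product of the
single-mutant shifts; deviations from unity quantify energetic coupling,
expressed as a free energy

    ddG = RT * ln(Omega),  T = 298 K.

Because whole-cell EC50 is a composite of binding and gating equilibria,
these energies rank couplings rather than measure a single equilibrium —
the same caveat that applies to any EC50-based cycle.

Uncertainty: the SD on ddG is propagated from the relative SDs of the
member EC50s in quadrature, scaled by |ddG|, with the WT term entering
k−1 times (once per appearance of EC50(WT) in the Omega numerator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from mutcycle.dose_response import (
    ConstructSummary,
    FoldChange,
    fold_from_ratio,
    round_sig,
)

__all__ = [
    "RT_KJ_PER_MOL",
    "CouplingCycle",
    "CouplingResult",
    "CycleDefinition",
    "predicted_independent_fold",
    "compute_omega",
    "coupling_energy",
    "propagate_coupling_sd",
    "evaluate_cycle",
    "build_cycle_table",
    "read_cycle_yaml",
]

#: R*T in kJ/mol at T = 298 K with R = 8.314 J/(mol K).
RT_KJ_PER_MOL = 8.314 * 298.0 / 1000.0


@dataclass(frozen=True)
class CouplingCycle:
    """The constructs forming one mutant cycle.

    ``singles`` holds the k >= 2 individual perturbations; ``combined``
    carries all of them together.  A paired gamma/delta mutation (one
    mutation in each of two subunits) enters as its two single-subunit
    constructs, since the independence prediction multiplies over every
    individual perturbation.
    """

    wt: ConstructSummary
    singles: tuple[ConstructSummary, ...]
    combined: ConstructSummary

    def __post_init__(self) -> None:
        if len(self.singles) < 1:
            raise ValueError("a cycle needs at least one single perturbation")
        object.__setattr__(self, "singles", tuple(self.singles))

    @property
    def k(self) -> int:
        return len(self.singles)

    def _require_functional(self, include_combined: bool = True) -> None:
        members = (self.wt, *self.singles) + ((self.combined,) if include_combined else ())
        for m in members:
            if not m.is_functional:
                raise ValueError(
                    f"cycle member {m.construct!r} is non-functional ({m.status})"
                )


@dataclass(frozen=True)
class CouplingResult:
    """One row of a coupling table.

    ``observed_fold``/``omega``/``ddg``/``ddg_sd`` are ``None`` when the
    combined construct is non-functional (the independence prediction is
    still defined from the singles).
    """

    cycle_id: str
    observed_fold: FoldChange | None
    predicted_fold: FoldChange
    omega: float | None
    ddg: float | None
    ddg_sd: float | None


def predicted_independent_fold(cycle: CouplingCycle) -> FoldChange:
    """Fold change expected if the perturbations acted independently.

    The independent prediction for the combined EC50 is
    ``EC50(WT) * prod_i (EC50(mut_i)/EC50(WT))``; the fold is the product
    of the single-mutant EC50 ratios pushed through the gain/loss
    convention.
    """
    cycle._require_functional(include_combined=False)
    ratio = math.prod(s.ec50_mean / cycle.wt.ec50_mean for s in cycle.singles)
    return fold_from_ratio(ratio)


def compute_omega(cycle: CouplingCycle) -> float:
    """Generalized interaction factor Omega (see module docstring)."""
    cycle._require_functional()
    k = cycle.k
    ec_wt = cycle.wt.ec50_mean
    ec_comb = cycle.combined.ec50_mean
    denom = math.prod(s.ec50_mean for s in cycle.singles)
    for label, value in [(cycle.wt.construct, ec_wt), (cycle.combined.construct, ec_comb)] + [
        (s.construct, s.ec50_mean) for s in cycle.singles
    ]:
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"EC50 of {label!r} must be positive, got {value!r}")
    return ec_wt ** (k - 1) * ec_comb / denom


def coupling_energy(omega: float) -> float:
    """Coupling free energy ddG = RT * ln(Omega) in kJ/mol (T = 298 K)."""
    if not (omega > 0) or not math.isfinite(omega):
        raise ValueError(f"Omega must be positive and finite, got {omega!r}")
    return RT_KJ_PER_MOL * math.log(omega)


def propagate_coupling_sd(cycle: CouplingCycle, ddg: float) -> float:
    """Propagated SD of the coupling energy, in kJ/mol.

    Relative EC50 SDs of all cycle members are combined in quadrature and
    scaled by |ddG|; the WT relative SD enters k−1 times.  At Omega = 1
    (ddG = 0) the propagated SD is zero by construction.
    """
    cycle._require_functional()
    members = [(cycle.wt, cycle.k - 1), (cycle.combined, 1)] + [
        (s, 1) for s in cycle.singles
    ]
    rel2 = 0.0
    for summary, weight in members:
        if weight == 0:
            continue
        if not math.isfinite(summary.ec50_sd):
            raise ValueError(f"missing EC50 SD for {summary.construct!r}")
        rel2 += weight * (summary.ec50_sd / summary.ec50_mean) ** 2
    return abs(ddg) * math.sqrt(rel2)


def evaluate_cycle(cycle: CouplingCycle, cycle_id: str = "") -> CouplingResult:
    """Evaluate one cycle: observed/predicted folds, Omega, ddG ± SD.

    A non-functional combined construct yields a predicted-only result.
    """
    predicted = predicted_independent_fold(cycle)
    if not cycle.combined.is_functional:
        return CouplingResult(cycle_id, None, predicted, None, None, None)
    observed = fold_from_ratio(cycle.combined.ec50_mean / cycle.wt.ec50_mean)
    omega = compute_omega(cycle)
    ddg = coupling_energy(omega)
    sd = propagate_coupling_sd(cycle, ddg)
    return CouplingResult(cycle_id, observed, predicted, omega, ddg, sd)


@dataclass(frozen=True)
class CycleDefinition:
    """A cycle referenced by construct labels (resolved against summaries)."""

    cycle_id: str
    single_labels: tuple[str, ...]
    combined_label: str
    wt_label: str = "WT"


def _rounded(s: ConstructSummary, sig: int = 3) -> ConstructSummary:
    if not s.is_functional:
        return s
    return ConstructSummary(
        construct=s.construct,
        ec50_mean=round_sig(s.ec50_mean, sig),
        ec50_sd=round_sig(s.ec50_sd, sig),
        hill_mean=round_sig(s.hill_mean, sig),
        hill_sd=round_sig(s.hill_sd, sig),
        n=s.n,
        status=s.status,
    )


def build_cycle_table(
    summaries: Mapping[str, ConstructSummary] | Iterable[ConstructSummary],
    cycles: Sequence[CycleDefinition],
    mode: str = "unrounded",
) -> pd.DataFrame:
    """Evaluate a list of cycle definitions into a coupling table.

    Parameters
    ----------
    summaries
        Construct summaries, by label or as an iterable.
    cycles
        Cycle definitions; the order of ``single_labels`` is immaterial.
    mode
        ``"unrounded"`` computes from the summaries as given (research
        mode); ``"printed"`` first rounds every EC50 mean/SD to 3
        significant figures, mimicking arithmetic done from a published
        table's displayed values.

    Returns a DataFrame with one row per cycle: observed and predicted
    folds (display strings plus numeric magnitude/direction), Omega, ddG
    and its SD.  Columns are NaN for predicted-only (non-functional
    combined) rows.
    """
    if mode not in ("unrounded", "printed"):
        raise ValueError(f"mode must be 'unrounded' or 'printed', got {mode!r}")
    if not isinstance(summaries, Mapping):
        summaries = {s.construct: s for s in summaries}

    def lookup(label: str) -> ConstructSummary:
        try:
            s = summaries[label]
        except KeyError:
            raise KeyError(f"cycle references undefined construct {label!r}") from None
        return _rounded(s) if mode == "printed" else s

    rows = []
    for cdef in cycles:
        cycle = CouplingCycle(
            wt=lookup(cdef.wt_label),
            singles=tuple(lookup(lbl) for lbl in cdef.single_labels),
            combined=lookup(cdef.combined_label),
        )
        res = evaluate_cycle(cycle, cycle_id=cdef.cycle_id)
        rows.append(
            {
                "cycle_id": res.cycle_id,
                "combined": cdef.combined_label,
                "observed_fold": str(res.observed_fold) if res.observed_fold else None,
                "observed_magnitude": res.observed_fold.magnitude
                if res.observed_fold
                else math.nan,
                "predicted_fold": str(res.predicted_fold),
                "predicted_magnitude": res.predicted_fold.magnitude,
                "omega": res.omega if res.omega is not None else math.nan,
                "ddg_kj_mol": res.ddg if res.ddg is not None else math.nan,
                "ddg_sd_kj_mol": res.ddg_sd if res.ddg_sd is not None else math.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cycle_id",
            "combined",
            "observed_fold",
            "observed_magnitude",
            "predicted_fold",
            "predicted_magnitude",
            "omega",
            "ddg_kj_mol",
            "ddg_sd_kj_mol",
        ],
    )


def read_cycle_yaml(path) -> list[CycleDefinition]:
    """Read cycle definitions from YAML.

    Format::

        cycles:
          - id: E45A_P272G
            wt: WT            # optional, defaults to WT
            singles: [aE45A, aP272G]
            combined: aE45A+aP272G
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = []
    for entry in doc["cycles"]:
        out.append(
            CycleDefinition(
                cycle_id=str(entry["id"]),
                wt_label=str(entry.get("wt", "WT")),
                single_labels=tuple(str(s) for s in entry["singles"]),
                combined_label=str(entry["combined"]),
            )
        )
    return out
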