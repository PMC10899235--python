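"""Seeded synthetic TEVC panels and toy C5-symmetric pentamer structures.

The dose–response generator emulates the study conditions of a
two-electrode voltage-clamp mutagenesis screen: each construct is
characterised in ~8 oocytes, each oocyte yields peak currents on a
half-log concentration grid bracketing EC50, per-oocyte EC50 varies
lognormally between oocytes (~19 % CV, matching the wild-type
9.40 ± 1.82 µM spread), and peak currents carry multiplicative Gaussian
measurement noise (7 % CV by default).  Hill slope and maximal current
are held fixed within a panel; only EC50 varies between oocytes, since
the EC50 spread is the quantity the downstream aggregation consumes.

The structure generator places residue "rings" with exact C5 symmetry
about the z axis, so every radial distance, interatomic distance and the
pore axis itself have closed-form ground truth.  What these fixtures do
not emulate: experimental coordinate error, deviations from perfect
symmetry, side-chain rotamers.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from mutcycle.dose_response import ConcentrationResponse, hill_current
from mutcycle.structure_geometry import PentamerStructure

__all__ = [
    "HillTruth",
    "DoseDesign",
    "RingSpec",
    "PanelDataset",
    "default_concentration_grid",
    "simulate_oocyte_responses",
    "generate_panel",
    "build_synthetic_pentamer",
    "default_pentamer_rings",
]

#: Wild-type regime used as generator default: EC50 9.40 µM, Hill 1.78.
WT_EC50_UM = 9.40
WT_HILL = 1.78


@dataclass(frozen=True)
class HillTruth:
    """Ground-truth Hill parameters for one construct."""

    ec50_true: float = WT_EC50_UM
    hill_true: float = WT_HILL
    imax_true: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ec50_true", "hill_true", "imax_true"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be positive, got {v!r}")


@dataclass(frozen=True)
class DoseDesign:
    """Experimental design for a simulated panel.

    ``concentrations=None`` uses a per-construct half-log grid of 8
    points spanning EC50/30 … 30·EC50.  CVs are fractions in [0, 1).
    """

    concentrations: np.ndarray | None = None
    n_oocytes: int = 8
    inter_oocyte_cv: float = 0.19
    noise_cv: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentrations is not None:
            c = np.asarray(self.concentrations, dtype=float)
            bad = c[c <= 0]
            if bad.size:
                raise ValueError(f"non-positive concentration not allowed: {bad[0]!r} µM")
            if not np.all(np.diff(c) > 0):
                raise ValueError("concentrations must be strictly increasing")
            object.__setattr__(self, "concentrations", c)
        if self.n_oocytes < 1:
            raise ValueError("n_oocytes must be >= 1")
        for name in ("inter_oocyte_cv", "noise_cv"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {v!r}")


def default_concentration_grid(
    ec50: float, n_points: int = 8, span: float = 30.0
) -> np.ndarray:
    """Half-log-style grid of ``n_points`` spanning ec50/span … ec50*span."""
    return np.geomspace(ec50 / span, ec50 * span, n_points)


def _lognormal_sigma(cv: float) -> float:
    # lognormal with median exp(mu): CV^2 = exp(sigma^2) - 1
    return math.sqrt(math.log(1.0 + cv * cv))


def simulate_oocyte_responses(
    truth: HillTruth,
    design: DoseDesign,
    construct: str = "WT",
    rng: np.random.Generator | None = None,
) -> list[ConcentrationResponse]:
    """Simulate one construct's panel of per-oocyte recordings.

    Per-oocyte EC50 is lognormal with median ``truth.ec50_true`` and
    coefficient of variation ``design.inter_oocyte_cv``; each peak
    current is the Hill response times (1 + eps), eps ~ N(0, noise_cv),
    clipped at zero.  Deterministic for a fixed ``design.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    conc = (
        design.concentrations
        if design.concentrations is not None
        else default_concentration_grid(truth.ec50_true)
    )
    sigma = _lognormal_sigma(design.inter_oocyte_cv)
    out = []
    for i in range(design.n_oocytes):
        ec50_i = truth.ec50_true * math.exp(sigma * rng.standard_normal()) if sigma else truth.ec50_true
        ideal = hill_current(conc, ec50_i, truth.hill_true, truth.imax_true)
        noise = 1.0 + design.noise_cv * rng.standard_normal(conc.size) if design.noise_cv else 1.0
        currents = np.clip(ideal * noise, 0.0, None)
        out.append(
            ConcentrationResponse(
                construct=construct,
                oocyte_id=f"{construct}-{i + 1:02d}",
                concentrations=conc,
                currents=currents,
            )
        )
    return out


@dataclass
class PanelDataset:
    """Simulated recordings for a panel of constructs."""

    responses: dict[str, list[ConcentrationResponse]]
    seed: int

    @property
    def constructs(self) -> list[str]:
        return list(self.responses)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, recs in self.responses.items():
            for r in recs:
                for c, i in zip(r.concentrations, r.currents):
                    rows.append((label, r.oocyte_id, c, i))
        return pd.DataFrame(
            rows, columns=["construct", "oocyte_id", "concentration_uM", "current"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_panel(
    panel_config: Mapping[str, HillTruth | None],
    design: DoseDesign,
) -> PanelDataset:
    """Simulate a multi-construct panel.

    ``panel_config`` maps construct label to its ground truth; a value of
    ``None`` marks a non-responsive (NR) construct whose traces are all
    zero.  A ``"WT"`` entry is required, as every downstream quantity is
    referenced to wild type.  Construct streams are seeded independently
    (spawned from ``design.seed``) so a panel is reproducible regardless
    of construct order.
    """
    if "WT" not in panel_config:
        raise ValueError("panel configuration must include a 'WT' construct")
    root = np.random.SeedSequence(design.seed)
    children = root.spawn(len(panel_config))
    responses: dict[str, list[ConcentrationResponse]] = {}
    for (label, truth), child in zip(sorted(panel_config.items()), children):
        rng = np.random.default_rng(child)
        if truth is None:  # NR construct: no agonist-induced current
            conc = (
                design.concentrations
                if design.concentrations is not None
                else default_concentration_grid(WT_EC50_UM)
            )
            responses[label] = [
                ConcentrationResponse(
                    construct=label,
                    oocyte_id=f"{label}-{i + 1:02d}",
                    concentrations=conc,
                    currents=np.zeros_like(conc),
                )
                for i in range(design.n_oocytes)
            ]
        else:
            responses[label] = simulate_oocyte_responses(
                truth, design, construct=label, rng=rng
            )
    # restore caller's ordering
    responses = {label: responses[label] for label in panel_config}
    return PanelDataset(responses=responses, seed=design.seed)


# ---------------------------------------------------------------------------
# synthetic pentamers


@dataclass(frozen=True)
class RingSpec:
    """One symmetric residue ring of the toy pentamer.

    Every chain receives one residue ``resname``/``resnum`` whose CA sits
    at (radius, height) on its azimuth; a pseudo side-chain atom (CB) is
    placed at the same radius 1.5 Å higher, so every atom's distance from
    the z axis equals the ring radius exactly.
    """

    resnum: int
    radius: float
    height: float
    resname: str = "ALA"
    n_fold: int = 5

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"ring radius must be >= 0, got {self.radius!r}")
        if self.n_fold < 1:
            raise ValueError("n_fold must be >= 1")


def default_pentamer_rings() -> list[RingSpec]:
    """A pore-lining-helix-like bundle: radii ~8–10 Å over a ~36 Å span.

    Residue numbers 246–270 sketch an M2 segment; the height spread
    dominates the radial spread so the principal axis of the CA set is
    the z (pore) axis.
    """
    specs = []
    for i, resnum in enumerate(range(246, 271, 3)):
        specs.append(
            RingSpec(
                resnum=resnum,
                radius=8.0 + 0.25 * i,
                height=-18.0 + 4.5 * i,
            )
        )
    return specs


def build_synthetic_pentamer(
    rings: Iterable[RingSpec],
    name: str = "synthetic-pentamer",
) -> PentamerStructure:
    """Build an exactly C_n-symmetric structure from ring specifications.

    Chains are labelled A, B, C, … around the z axis; each ring places
    one residue per chain with a CA and a pseudo side-chain CB atom, both
    at the ring radius.  Degenerate radius 0 collapses the ring onto the
    axis (still valid).
    """
    rings = list(rings)
    if not rings:
        raise ValueError("need at least one ring")
    n_fold = rings[0].n_fold
    if any(r.n_fold != n_fold for r in rings):
        raise ValueError("all rings must share the same n_fold")
    chains = string.ascii_uppercase[:n_fold]
    rows = []
    for ring in rings:
        for j, chain in enumerate(chains):
            theta = 2.0 * math.pi * j / n_fold
            x = ring.radius * math.cos(theta)
            y = ring.radius * math.sin(theta)
            rows.append((chain, ring.resnum, ring.resname, "CA", "C", x, y, ring.height))
            rows.append((chain, ring.resnum, ring.resname, "CB", "C", x, y, ring.height + 1.5))
    atoms = pd.DataFrame(
        rows, columns=["chain", "resnum", "resname", "atom", "element", "x", "y", "z"]
    )
    return PentamerStructure(atoms, name=name)
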