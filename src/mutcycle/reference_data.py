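"""Published TEVC reference measurements for the Torpedo muscle nAChR.

Construct summaries (EC50 mean ± SD in µM, Hill slope mean ± SD,
replicate count) for wild type and the ECD–TMD interface mutants, as
reported from whole-cell two-electrode voltage-clamp recordings in
Xenopus oocytes, together with the mutant-cycle compositions evaluated
on them.  These are inputs to the coupling analysis, kept here so the
pipeline can reproduce the published coupling table without external
files.

Label scheme: Greek subunit letters are transliterated (α→a, β→b, γ→g,
δ→d), e.g. ``aE45R`` is the alpha-subunit E45R mutant and ``gG182A`` the
gamma-subunit G182A mutant.  Combined constructs join their members with
``+``.  Paired gamma/delta mutations (the same position mutated in both
complementary subunits) appear both as the pair construct (measured) and
as their single-subunit members, because the independence prediction
multiplies over individual perturbations.

Statuses: ``NR`` no agonist response, ``NE`` no surface expression.
"""

from __future__ import annotations

from mutcycle.dose_response import ConstructSummary
from mutcycle.mutant_cycle import CycleDefinition

__all__ = ["construct_summaries", "cycle_definitions"]

# construct -> (ec50_mean, ec50_sd, hill_mean, hill_sd, n) or status string
_SUMMARIES: dict[str, tuple | str] = {
    "WT": (9.40, 1.82, 1.78, 0.35, 8),
    # intra-subunit gating interface
    "aE45R": (0.600, 0.316, 1.39, 0.21, 8),
    "aE45A": (25.1, 5.5, 1.83, 0.31, 8),
    "aE45K": "NR",
    "aV46A": (108, 21, 2.00, 0.41, 8),
    "aR209Q": "NE",
    "aR209E": "NE",
    "aI264A": (28.5, 6.3, 1.45, 0.19, 10),
    "aP265A": (2.10, 0.65, 1.58, 0.35, 9),
    "aP265G": (19.8, 5.5, 1.85, 0.54, 8),
    "aP272G": (27.1, 4.9, 1.63, 0.15, 10),
    # inter-subunit gating interface
    "aS266A": (41.6, 7.3, 1.58, 0.20, 8),
    "aT267A": (27.4, 3.1, 1.57, 0.17, 8),
    "aS268A": (2.21, 0.33, 1.77, 0.28, 8),
    "aS269A": (3.83, 0.30, 1.97, 0.47, 8),
    "aS266A+aT267A+aS268A+aS269A": (4.32, 1.42, 2.12, 0.26, 8),
    "aS266G+aT267G+aS268G+aS269G": (14.3, 2.2, 1.79, 0.13, 8),
    "bE272G+bT273G+bS274G+bL275G": (14.0, 1.5, 1.85, 0.18, 14),
    "dE280G+dT281G+dA282G+dL283G": (21.5, 3.2, 1.63, 0.15, 7),
    "gE275G+gT276G+gS277G+gL278G": (19.7, 2.6, 1.51, 0.18, 8),
    "abdg(STSS->GGGG)": (16.2, 3.4, 2.14, 0.47, 7),
    "gG182A": (23.4, 2.8, 1.53, 0.26, 8),
    "dG188A": (19.3, 3.5, 1.59, 0.20, 8),
    "gG182A+dG188A": (31.0, 2.1, 1.68, 0.30, 9),
    "gE183A": (15.9, 3.3, 1.69, 0.15, 8),
    "dE189A": (10.2, 1.1, 1.80, 0.21, 8),
    "gE183A+dE189A": (16.3, 4.0, 1.50, 0.51, 8),
    "gK218A": (2.39, 0.66, 1.91, 0.25, 8),
    "dK224A": (4.24, 0.98, 1.84, 0.26, 9),
    "gK218A+dK224A": (0.956, 0.434, 2.14, 0.57, 9),
    "gP219A": (11.8, 1.5, 2.07, 0.56, 8),
    "dP225A": (12.0, 1.5, 1.93, 0.59, 8),
    "gP219A+dP225A": (12.0, 1.4, 1.67, 0.59, 8),
    "gL220A": (8.83, 2.14, 1.81, 0.11, 8),
    "dL226A": (4.48, 0.70, 2.20, 0.35, 8),
    "gL220A+dL226A": (6.42, 0.81, 1.87, 0.33, 8),
    "gF221A": (17.6, 3.0, 1.72, 0.28, 8),
    "dF227A": (5.67, 0.78, 2.10, 0.71, 8),
    "gF221A+dF227A": (18.0, 7.2, 2.04, 0.25, 8),
    # combined constructs of the coupling table, intra-subunit
    "aE45R+aR209Q": (9.16, 2.47, 1.92, 0.40, 8),
    "aE45R+aR209E": (9.80, 2.23, 1.72, 0.09, 8),
    "aE45A+aV46A": "NR",
    "aE45A+aP272G": (55.8, 8.2, 1.49, 0.18, 8),
    "aV46A+aI264A": (143, 27, 1.69, 0.28, 8),
    "aV46A+aP265A": (32.2, 6.0, 2.01, 0.26, 8),
    "aV46A+aP265G": (34.2, 3.6, 1.99, 0.22, 7),
    "aV46A+aP272G": (142, 33, 2.29, 0.50, 8),
    "aI264A+aP265G": (6.52, 1.32, 1.42, 0.33, 8),
    "aI264A+aP272G": (54.5, 9.8, 1.59, 0.38, 9),
    "aE45A+aV46A+aP272G": "NR",
    "aV46A+aI264A+aP265G": (7.80, 1.20, 1.66, 0.26, 8),
    "aV46A+aI264A+aP272G": (105, 14, 2.11, 0.52, 8),
    # combined constructs, inter-subunit
    "aS266A+gG182A+dG188A": (46.3, 6.7, 2.15, 0.23, 8),
    "aS266A+gE183A+dE189A": (28.7, 4.8, 1.87, 0.37, 8),
    "aT267A+gG182A+dG188A": (33.2, 3.5, 2.25, 0.54, 8),
    "aT267A+gF221A+dF227A": "NR",
    "aS268A+gG182A+dG188A": (11.0, 3.1, 1.82, 0.49, 8),
    "aS268A+gK218A+dK224A": (0.486, 0.126, 2.22, 0.45, 8),
    "aS268P+gG182A+dG188A": (6.50, 2.47, 1.63, 0.55, 8),
    "aS269A+gG182A+dG188A": "NR",
    "aS269A+gK218A+dK224A": (0.439, 0.126, 2.03, 0.73, 4),
    "aS269A+gL220A+dL226A": "NR",
    "aS266A+aT267A+gG182A+dG188A": (31.5, 4.6, 2.13, 0.32, 9),
    "aS266A+aT267A+gE183A+dE189A": (27.3, 9.2, 2.30, 0.69, 8),
    "aS268A+aS269A+gG182A+dG188A": (5.05, 0.97, 1.96, 0.72, 8),
    "aS268A+aS269A+gK218A+dK224A": (0.176, 0.064, 2.99, 0.92, 5),
    "aSTGG4+gG182A": (20.6, 8.2, 1.65, 0.22, 8),
    "aSTGG4+dG188A": (22.1, 2.4, 1.87, 0.21, 8),
    "aSTGG4+gG182A+dG188A": (30.1, 5.9, 1.81, 0.54, 8),
}

# cycle id -> (singles, combined); WT implied.  Paired gamma/delta
# mutations are decomposed into their single-subunit members.
_CYCLES: dict[str, tuple[tuple[str, ...], str]] = {
    # aE45R+aR209Q / aE45R+aR209E are not expressible as cycles here:
    # the R209 single mutants do not reach the cell surface (NE).
    "E45A_V46A": (("aE45A", "aV46A"), "aE45A+aV46A"),
    "E45A_P272G": (("aE45A", "aP272G"), "aE45A+aP272G"),
    "V46A_I264A": (("aV46A", "aI264A"), "aV46A+aI264A"),
    "V46A_P265A": (("aV46A", "aP265A"), "aV46A+aP265A"),
    "V46A_P265G": (("aV46A", "aP265G"), "aV46A+aP265G"),
    "V46A_P272G": (("aV46A", "aP272G"), "aV46A+aP272G"),
    "I264A_P265G": (("aI264A", "aP265G"), "aI264A+aP265G"),
    "I264A_P272G": (("aI264A", "aP272G"), "aI264A+aP272G"),
    "E45A_V46A_P272G": (("aE45A", "aV46A", "aP272G"), "aE45A+aV46A+aP272G"),
    "V46A_I264A_P265G": (("aV46A", "aI264A", "aP265G"), "aV46A+aI264A+aP265G"),
    "V46A_I264A_P272G": (("aV46A", "aI264A", "aP272G"), "aV46A+aI264A+aP272G"),
    "S266A_G182A.G188A": (("aS266A", "gG182A", "dG188A"), "aS266A+gG182A+dG188A"),
    "S266A_E183A.E189A": (("aS266A", "gE183A", "dE189A"), "aS266A+gE183A+dE189A"),
    "T267A_G182A.G188A": (("aT267A", "gG182A", "dG188A"), "aT267A+gG182A+dG188A"),
    "T267A_F221A.F227A": (("aT267A", "gF221A", "dF227A"), "aT267A+gF221A+dF227A"),
    "S268A_G182A.G188A": (("aS268A", "gG182A", "dG188A"), "aS268A+gG182A+dG188A"),
    "S268A_K218A.K224A": (("aS268A", "gK218A", "dK224A"), "aS268A+gK218A+dK224A"),
    "S269A_G182A.G188A": (("aS269A", "gG182A", "dG188A"), "aS269A+gG182A+dG188A"),
    "S269A_K218A.K224A": (("aS269A", "gK218A", "dK224A"), "aS269A+gK218A+dK224A"),
    "S269A_L220A.L226A": (("aS269A", "gL220A", "dL226A"), "aS269A+gL220A+dL226A"),
    "S266A.T267A_G182A.G188A": (
        ("aS266A", "aT267A", "gG182A", "dG188A"),
        "aS266A+aT267A+gG182A+dG188A",
    ),
    "S266A.T267A_E183A.E189A": (
        ("aS266A", "aT267A", "gE183A", "dE189A"),
        "aS266A+aT267A+gE183A+dE189A",
    ),
    "S268A.S269A_G182A.G188A": (
        ("aS268A", "aS269A", "gG182A", "dG188A"),
        "aS268A+aS269A+gG182A+dG188A",
    ),
    "S268A.S269A_K218A.K224A": (
        ("aS268A", "aS269A", "gK218A", "dK224A"),
        "aS268A+aS269A+gK218A+dK224A",
    ),
    # the quadruple Ser/Thr->Gly M2-M3 construct treated as one perturbation
    "STGG4_G182A": (("aS266G+aT267G+aS268G+aS269G", "gG182A"), "aSTGG4+gG182A"),
    "STGG4_G188A": (("aS266G+aT267G+aS268G+aS269G", "dG188A"), "aSTGG4+dG188A"),
    "STGG4_G182A.G188A": (
        ("aS266G+aT267G+aS268G+aS269G", "gG182A", "dG188A"),
        "aSTGG4+gG182A+dG188A",
    ),
}


def construct_summaries() -> dict[str, ConstructSummary]:
    """The reference construct-summary table, keyed by construct label."""
    out: dict[str, ConstructSummary] = {}
    for label, entry in _SUMMARIES.items():
        if isinstance(entry, str):
            out[label] = ConstructSummary(construct=label, status=entry)
        else:
            ec50, ec50_sd, hill, hill_sd, n = entry
            out[label] = ConstructSummary(
                construct=label,
                ec50_mean=float(ec50),
                ec50_sd=float(ec50_sd),
                hill_mean=float(hill),
                hill_sd=float(hill_sd),
                n=int(n),
            )
    return out


def cycle_definitions() -> list[CycleDefinition]:
    """Mutant-cycle compositions for the reference coupling table.

    The three cycles built on gamma-G182I / delta-G188I backgrounds are
    omitted: their single-mutant summaries are not part of this table.
    """
    return [
        CycleDefinition(cycle_id=cid, single_labels=singles, combined_label=combined)
        for cid, (singles, combined) in _CYCLES.items()
    ]
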