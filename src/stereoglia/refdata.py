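"""Published reference values bundled as worked-example constants.

These are the per-side population means (mean +- SEM) reported by the
mouse infraorbital-nerve (IoN) transection study of trigeminal microglia
that this package's simulator emulates: length density of processes
(L_V, mm/mm^3), numerical density of cell bodies (N_V, cells/mm^3) and
mean process length per cell (L_N), sorted by group (C = control,
IoN = nerve-transected), immunostain (DAB chromogen vs immunofluorescence)
and brain-stem side (L/R; R is the deafferented side in IoN animals);
plus the pooled cell-body volume means and the single-cell digital
reconstruction means for the same material.

``derived_percentages`` recomputes every headline percentage of that
study from these stored means alone — a desk-scale worked example whose
arithmetic (which sides enter each ratio, which means are pooled) is
documented per statistic.  Note the published L_N column is a per-animal
mean of ratios, so L_N rows do not equal the ratio of the printed L_V
and N_V means — no consistency between the three columns is asserted
here (the pipeline enforces it on its own computed rows instead).

The L_N column header in the source reads mm/cell; the magnitudes
(279-825) are micrometres and are treated as um/cell throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TableRow",
    "TABLE1",
    "SOMA_VOLUMES",
    "RECONSTRUCTION_LN",
    "REPORTED_MEAN_CE",
    "DerivedStat",
    "derived_percentages",
    "excluded_comparisons",
    "round_half_away",
]


@dataclass(frozen=True)
class TableRow:
    group: str  # "C" or "IoN"
    stain: str  # "DAB" or "IF"
    side: str  # "L" or "R"
    lv: float  # mm/mm^3
    lv_sem: float
    nv: float  # cells/mm^3
    nv_sem: float
    ln: float  # um/cell
    ln_sem: float


TABLE1: dict[tuple[str, str, str], TableRow] = {
    (r.group, r.stain, r.side): r
    for r in [
        TableRow("C", "DAB", "L", 5779, 348, 10311, 107, 561, 34),
        TableRow("C", "DAB", "R", 5708, 209, 10999, 418, 538, 35),
        TableRow("C", "IF", "L", 8427, 665, 10696, 679, 825, 29),
        TableRow("C", "IF", "R", 7968, 560, 9922, 576, 809, 24),
        TableRow("IoN", "DAB", "L", 5615, 564, 11069, 524, 525, 82),
        TableRow("IoN", "DAB", "R", 14128, 209, 49263, 2397, 279, 25),
        TableRow("IoN", "IF", "L", 7632, 764, 9652, 869, 805, 27),
        TableRow("IoN", "IF", "R", 18946, 534, 53584, 2279, 361, 16),
    ]
}

#: Pooled cell-body volumes, um^3 (mean, sd, n cells).
SOMA_VOLUMES = {
    "control": (149.0, 74.0, 110),
    "deafferented": (249.0, 118.0, 283),
}

#: Mean process length per cell from single-cell digital reconstructions
#: in two control cases, um (mean, sem), by side.
RECONSTRUCTION_LN = {"R": (592.0, 33.0), "L": (599.0, 31.0)}

#: Reported mean coefficients of error of the L_V and N_V estimates.
REPORTED_MEAN_CE = {"lv": 0.086, "nv": 0.133}


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class DerivedStat:
    key: str
    value_pct: int
    raw_pct: float
    description: str


def _mean(*vals: float) -> float:
    return sum(vals) / len(vals)


def derived_percentages(
    table: dict | None = None,
    soma_volumes: dict | None = None,
    reconstruction_ln: dict | None = None,
) -> dict[str, DerivedStat]:
    """Recompute the headline percentages from the stored means.

    Pooling conventions, fixed per statistic:

    * deafferentation ratios (N_V increase per stain, L_V increase, L_N
      remaining) compare the deafferented side to the contralateral side
      of the same (IoN) animals; the L_V increase is the mean of the two
      per-stain ratios ("about 250% in both");
    * between-stain differences pool the two control sides per stain and
      express the difference relative to the larger (DAB for N_V where it
      is larger, IF for L_V), matching how the study words them;
    * the reconstruction comparison pools both control IF sides and both
      reconstruction sides;
    * the soma excess is the deafferented pooled mean over the control
      pooled mean.
    """
    t = TABLE1 if table is None else table
    sv = SOMA_VOLUMES if soma_volumes is None else soma_volumes
    rl = RECONSTRUCTION_LN if reconstruction_ln is None else reconstruction_ln

    nv_dab = 100.0 * t[("IoN", "DAB", "R")].nv / t[("IoN", "DAB", "L")].nv
    nv_if = 100.0 * t[("IoN", "IF", "R")].nv / t[("IoN", "IF", "L")].nv
    lv_ratio = 100.0 * _mean(
        t[("IoN", "DAB", "R")].lv / t[("IoN", "DAB", "L")].lv,
        t[("IoN", "IF", "R")].lv / t[("IoN", "IF", "L")].lv,
    )
    ln_dab = 100.0 * t[("IoN", "DAB", "R")].ln / t[("IoN", "DAB", "L")].ln
    ln_if = 100.0 * t[("IoN", "IF", "R")].ln / t[("IoN", "IF", "L")].ln

    nv_dab_c = _mean(t[("C", "DAB", "L")].nv, t[("C", "DAB", "R")].nv)
    nv_if_c = _mean(t[("C", "IF", "L")].nv, t[("C", "IF", "R")].nv)
    nv_stain = 100.0 * (nv_dab_c - nv_if_c) / nv_dab_c if nv_dab_c else 0.0

    lv_dab_c = _mean(t[("C", "DAB", "L")].lv, t[("C", "DAB", "R")].lv)
    lv_if_c = _mean(t[("C", "IF", "L")].lv, t[("C", "IF", "R")].lv)
    lv_stain = 100.0 * (lv_if_c - lv_dab_c) / lv_if_c if lv_if_c else 0.0

    ln_if_c = _mean(t[("C", "IF", "L")].ln, t[("C", "IF", "R")].ln)
    recon = _mean(rl["R"][0], rl["L"][0])
    recon_pct = 100.0 * (ln_if_c - recon) / ln_if_c if ln_if_c else 0.0

    soma_c, soma_d = sv["control"][0], sv["deafferented"][0]
    soma_pct = 100.0 * (soma_d - soma_c) / soma_c

    raw = {
        "nv_increase_dab_pct": (
            nv_dab,
            "N_V on the deafferented side vs contralateral, DAB material",
        ),
        "nv_increase_if_pct": (
            nv_if,
            "N_V on the deafferented side vs contralateral, immunofluorescence",
        ),
        "lv_increase_pct": (
            lv_ratio,
            "L_V on the deafferented side vs contralateral, mean of both stains",
        ),
        "ln_remaining_dab_pct": (
            ln_dab,
            "L_N remaining on the deafferented side, DAB material",
        ),
        "ln_remaining_if_pct": (
            ln_if,
            "L_N remaining on the deafferented side, immunofluorescence",
        ),
        "nv_stain_difference_pct": (
            nv_stain,
            "between-stain N_V difference on control material (negligible)",
        ),
        "lv_stain_difference_pct": (
            lv_stain,
            "L_V deficit of DAB relative to immunofluorescence, control material",
        ),
        "tvp_vs_reconstruction_pct": (
            recon_pct,
            "single-cell reconstruction L_N deficit vs population estimate",
        ),
        "soma_size_excess_pct": (
            soma_pct,
            "deafferented vs control mean cell-body volume",
        ),
    }
    return {
        k: DerivedStat(k, round_half_away(v), v, desc) for k, (v, desc) in raw.items()
    }


def excluded_comparisons() -> list[str]:
    """Comparisons that cannot be rederived from the stored means.

    The deafferented-side between-stain differences (reported as 4%, n.s.,
    and 26% for N_V and L_V) come from per-animal paired computations whose
    per-animal values were never published; no pooling of the per-side
    means reproduces them, so they are flagged rather than computed.
    """
    return [
        "deafferented-side between-stain N_V difference (reported 4%, n.s.): "
        "requires unpublished per-animal pairs",
        "deafferented-side between-stain L_V difference (reported 26%): "
        "requires unpublished per-animal pairs",
    ]
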