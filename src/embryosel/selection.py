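"""Per-patient embryo ranking and comparison of model-based selection
against standard visual-grade selection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = ["SelectionComparison", "rank_embryos", "compare_decisions", "sss_grade_key"]


@dataclass
class SelectionComparison:
    """Outcome of the per-patient decision comparison.

    Fractions are percentages; ties among equally graded top embryos are
    broken by lowest embryo id (flagged here because the choice is a
    convention, not data).
    """

    n_patients: int
    n_concordant: int
    n_discordant: int
    concordance_percent: float
    discordance_percent: float
    records: list[dict] = field(default_factory=list)
    tie_break_rule: str = "lowest embryo_id among equally ranked"

    def __post_init__(self) -> None:
        assert self.n_concordant + self.n_discordant == self.n_patients


def rank_embryos(embryos: Sequence, scorer: Callable) -> list:
    """Order one patient's embryos by descending model score.

    ``scorer(embryo)`` returns the ranking score; embryos it cannot score
    (raising ValueError/KeyError) are skipped. Ties break by lower
    ``embryo_id``.
    """
    scored = []
    for e in embryos:
        try:
            s = float(scorer(e))
        except (ValueError, KeyError):
            continue
        scored.append((s, e))
    if not scored:
        raise ValueError("no scoreable embryo for this patient")
    scored.sort(key=lambda t: (-t[0], _embryo_id(t[1])))
    return [e for _, e in scored]


def _embryo_id(e) -> str:
    return str(getattr(e, "embryo_id", e))


def sss_grade_key(grades) -> tuple:
    """Default visual-quality ordering: more Day-3 cells toward 8, lower
    fragmentation, better symmetry (smaller key = better embryo)."""
    return (
        abs(grades.n_d3 - 8),
        grades.frag_cat_d3,
        grades.symmetry_d3,
        grades.frag_cat_d2,
        grades.symmetry_d2,
        _embryo_id(grades),
    )


def compare_decisions(
    patients: Sequence[Sequence],
    sss_rule: Callable,
    model_scorer: Callable,
    min_embryos: int = 2,
) -> SelectionComparison:
    """Compare the standard choice with the model choice per patient.

    ``patients`` is a list of per-patient embryo lists. The standard choice
    is the minimum of ``sss_rule(embryo)`` (ties by lowest id); the model
    choice is the top of :func:`rank_embryos`. Patients with fewer than
    ``min_embryos`` embryos are excluded with a warning.
    """
    n_conc = 0
    n_disc = 0
    records = []
    for embryos in patients:
        if len(embryos) < min_embryos:
            warnings.warn(
                f"patient with {len(embryos)} embryo(s) excluded from comparison"
            )
            continue
        sss_choice = min(embryos, key=lambda e: (sss_rule(e), _embryo_id(e)))
        model_choice = rank_embryos(embryos, model_scorer)[0]
        same = _embryo_id(sss_choice) == _embryo_id(model_choice)
        n_conc += int(same)
        n_disc += int(not same)
        records.append(
            {
                "sss_choice": _embryo_id(sss_choice),
                "model_choice": _embryo_id(model_choice),
                "concordant": same,
            }
        )
    n = n_conc + n_disc
    if n == 0:
        raise ValueError("no patient had enough embryos to compare")
    return SelectionComparison(
        n_patients=n,
        n_concordant=n_conc,
        n_discordant=n_disc,
        concordance_percent=round(100.0 * n_conc / n, 1),
        discordance_percent=round(100.0 * n_disc / n, 1),
        records=records,
    )
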