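"""DIC-based selection over the fixed candidate set of selection models.

Nine candidate formulas combine the bare-ground proportion (b), vegetation
height (h) and their squares under marginality; when height was not
measured (the common-redstart case) the set reduces to the three formulas
that use bare ground only. Candidates are fixed a priori, never data-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .rsf_model import (
    Design,
    DicSummary,
    FitResult,
    MCMCConfig,
    ModelFormula,
    Priors,
    build_design,
    compute_dic,
    fit,
)

__all__ = ["candidate_formulas", "run_selection", "SelectionRow", "SelectionTable"]

_FULL_SET = (
    "b+b2+h+h2",
    "b+h+h2",
    "h+h2",
    "b+b2+h",
    "b+b2",
    "b+h",
    "b",
    "h",
    "intercept",
)
_NO_HEIGHT_SET = ("b+b2", "b", "intercept")


def candidate_formulas(include_height: bool = True) -> list[ModelFormula]:
    """The fixed candidate set, in canonical presentation order.

    With height measured there are nine formulas from the full quadratic
    b+b2+h+h2 down to the intercept-only null; without height only the
    three bare-ground formulas remain.
    """
    names = _FULL_SET if include_height else _NO_HEIGHT_SET
    return [ModelFormula.from_string(n) for n in names]


@dataclass
class SelectionRow:
    formula: ModelFormula
    dic_summary: DicSummary
    delta_dic: float
    rank: int


@dataclass
class SelectionTable:
    """Candidate models ranked by DIC (ascending)."""

    rows: list[SelectionRow]
    fits: dict[str, FitResult]
    designs: dict[str, Design]

    @property
    def best(self) -> SelectionRow:
        return self.rows[0]

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.best.formula.name]

    @property
    def best_design(self) -> Design:
        return self.designs[self.best.formula.name]

    def delta(self, formula_name: str) -> float:
        for r in self.rows:
            if r.formula.name == formula_name:
                return r.delta_dic
        raise KeyError(formula_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [r.formula.name for r in self.rows],
                "deviance": [r.dic_summary.d_bar for r in self.rows],
                "pD": [r.dic_summary.p_d for r in self.rows],
                "dDIC": [r.delta_dic for r in self.rows],
            }
        )


def run_selection(
    records,
    priors: Priors | None = None,
    config: MCMCConfig | None = None,
    include_height: bool | None = None,
    formulas: Iterable[ModelFormula] | None = None,
    keep_fits: bool = True,
) -> SelectionTable:
    """Fit every candidate model and rank by DIC.

    Each candidate is fitted with its own deterministic seed (base seed +
    candidate index) so the whole table reproduces from one integer.
    ``include_height=None`` auto-detects from the records (a height column
    with any missing value drops the height formulas). Ties in DIC are
    reported in fit order, not resolved.
    """
    priors = priors or Priors()
    config = config or MCMCConfig()
    if formulas is None:
        if include_height is None:
            df = records if isinstance(records, pd.DataFrame) else None
            if df is not None:
                include_height = bool(pd.notna(df["height"]).all())
            else:
                include_height = all(
                    r.covs.height == r.covs.height for r in records  # not NaN
                )
        formulas = candidate_formulas(include_height)
    formulas = list(formulas)

    entries: list[tuple[ModelFormula, DicSummary, FitResult, Design]] = []
    for i, formula in enumerate(formulas):
        design = build_design(records, formula)
        res = fit(design, priors, replace(config, seed=config.seed + i))
        entries.append((formula, compute_dic(res, design), res, design))

    best_dic = min(e[1].dic for e in entries)
    entries.sort(key=lambda e: e[1].dic)
    rows = [
        SelectionRow(
            formula=f, dic_summary=d, delta_dic=d.dic - best_dic, rank=r + 1
        )
        for r, (f, d, _, _) in enumerate(entries)
    ]
    return SelectionTable(
        rows=rows,
        fits={f.name: res for f, _, res, _ in entries} if keep_fits else {},
        designs={f.name: des for f, _, _, des in entries} if keep_fits else {},
    )
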