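"""NCI-60-style GI50 differential-sensitivity screen.

Cell lines are labelled by tissue and TP53 status (``nonsense``, ``WT``,
``other-mut``).  For every compound and tissue two ratios of group-mean
GI50 concentrations are computed:

    ratio_mut = mean GI50(other-mut) / mean GI50(nonsense)
    ratio_wt  = mean GI50(WT)        / mean GI50(nonsense)

and a compound is selected when ratio_mut > 4 and ratio_wt > 1.5 (strict
inequalities) in every required tissue — i.e. nonsense-mutant lines are
hit at markedly lower concentrations than both comparison groups.  Means
are arithmetic on the linear concentration scale by default; a geometric
(log-scale) mean is available since GI50 archives are often stored as
-log10 molar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GI50Matrix",
    "ScreenResult",
    "compute_ratios",
    "select_compounds",
    "ratio_plane_export",
    "read_gi50_tsv",
    "write_gi50_tsv",
    "T_MUT",
    "T_WT",
]

T_MUT = 4.0
T_WT = 1.5
STATUSES = ("nonsense", "WT", "other-mut")


@dataclass
class GI50Matrix:
    """Compound x cell-line GI50 concentrations (molar, linear scale).

    ``values``: DataFrame indexed by compound, columns are cell lines
    (NaN = missing).  ``labels``: DataFrame indexed by cell line with
    columns ``tissue`` and ``tp53_status``.
    """

    values: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.labels.index]
        if missing:
            raise ValueError(f"cell lines without labels: {missing}")
        for col in ("tissue", "tp53_status"):
            if col not in self.labels.columns:
                raise ValueError(f"labels missing column {col!r}")
        bad = set(self.labels["tp53_status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown tp53_status values: {sorted(bad)}")
        if (self.values.to_numpy(dtype=float) <= 0).any():
            raise ValueError("GI50 values must be > 0 where present")

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.labels.loc[self.values.columns, "tissue"]))


@dataclass
class ScreenResult:
    """Selection outcome: per-compound/tissue ratios and the selected set."""

    ratios: pd.DataFrame  # compound, tissue, ratio_mut, ratio_wt, evaluable, passes
    selected: list[str]
    t_mut: float
    t_wt: float
    tissues_required: list[str] = field(default_factory=list)


def _group_mean(values: pd.DataFrame, lines: list[str], log_mean: bool) -> pd.Series:
    sub = values[lines]
    if log_mean:
        return np.exp(np.log(sub).mean(axis=1, skipna=True))
    return sub.mean(axis=1, skipna=True)


def compute_ratios(matrix: GI50Matrix, log_mean: bool = False) -> pd.DataFrame:
    """Per-compound, per-tissue (ratio_mut, ratio_wt).

    Group means are taken over available values; a compound with no value
    in any nonsense line of a tissue is flagged unevaluable there (no
    ratios emitted).  A tissue lacking an entire status group across the
    panel is fatal.  ``log_mean=True`` switches to geometric means.
    """
    rows = []
    for tissue in matrix.tissues:
        lines = matrix.labels.index[
            (matrix.labels["tissue"] == tissue)
            & (matrix.labels.index.isin(matrix.values.columns))
        ]
        groups = {
            s: [l for l in lines if matrix.labels.loc[l, "tp53_status"] == s]
            for s in STATUSES
        }
        for s, ls in groups.items():
            if not ls:
                raise ValueError(f"tissue {tissue!r} has no cell line with status {s!r}")
        means = {s: _group_mean(matrix.values, ls, log_mean) for s, ls in groups.items()}
        nonsense = means["nonsense"]
        for compound in matrix.values.index:
            denom = nonsense[compound]
            evaluable = bool(np.isfinite(denom)) and denom > 0
            num_mut, num_wt = means["other-mut"][compound], means["WT"][compound]
            evaluable = evaluable and np.isfinite(num_mut) and np.isfinite(num_wt)
            rows.append(
                {
                    "compound": compound,
                    "tissue": tissue,
                    "ratio_mut": num_mut / denom if evaluable else np.nan,
                    "ratio_wt": num_wt / denom if evaluable else np.nan,
                    "evaluable": evaluable,
                }
            )
    return pd.DataFrame(rows)


def select_compounds(
    ratios: pd.DataFrame,
    t_mut: float = T_MUT,
    t_wt: float = T_WT,
    tissues_required: list[str] | None = None,
) -> ScreenResult:
    """Apply the two-ratio rule: selected iff ratio_mut > t_mut AND
    ratio_wt > t_wt in *every* required tissue (strict inequalities).

    An unevaluable tissue disqualifies the compound.  Selection can only
    shrink as thresholds increase.
    """
    ratios = ratios.copy()
    required = tissues_required or sorted(ratios["tissue"].unique())
    ratios["passes"] = (
        ratios["evaluable"]
        & (ratios["ratio_mut"] > t_mut)
        & (ratios["ratio_wt"] > t_wt)
    )
    selected = []
    for compound, grp in ratios.groupby("compound", sort=True):
        by_tissue = grp.set_index("tissue")["passes"]
        if all(t in by_tissue.index and bool(by_tissue[t]) for t in required):
            selected.append(compound)
    return ScreenResult(ratios=ratios, selected=selected,
                        t_mut=t_mut, t_wt=t_wt, tissues_required=list(required))


def ratio_plane_export(result: ScreenResult | pd.DataFrame) -> pd.DataFrame:
    """Scatter table (x = ratio_wt, y = ratio_mut), one row per evaluable
    compound per tissue, for plotting the selection plane."""
    ratios = result.ratios if isinstance(result, ScreenResult) else result
    ev = ratios[ratios["evaluable"]]
    return pd.DataFrame(
        {
            "compound": ev["compound"].to_numpy(),
            "tissue": ev["tissue"].to_numpy(),
            "x_ratio_wt": ev["ratio_wt"].to_numpy(),
            "y_ratio_mut": ev["ratio_mut"].to_numpy(),
        }
    )


def read_gi50_tsv(values_path: str | Path, labels_path: str | Path) -> GI50Matrix:
    """Read a GI50 matrix TSV (rows compounds, columns cell lines) plus a
    labels TSV (columns cell_line, tissue, tp53_status)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col="cell_line")
    return GI50Matrix(values=values, labels=labels)


def write_gi50_tsv(matrix: GI50Matrix, values_path: str | Path,
                   labels_path: str | Path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="compound")
    matrix.labels.to_csv(labels_path, sep="\t", index_label="cell_line")
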