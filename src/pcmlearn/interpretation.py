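"""Attribution of bioactivity to keyed compound substructures.

Two complementary procedures identify substructures driving potency and
selectivity, exploiting the fact that every fingerprint column is a concrete
circular substructure:

* *Predictive method* (model-based): a substructure is "virtually removed"
  from each compound containing it by zeroing its raw count (preprocessing is
  then re-applied), and the drop in the model's predicted pIC50 is recorded.
  The count-weighted mean of these differences is the substructure's average
  contribution; a positive sign is beneficial, negative deleterious. Because
  the model sees the whole descriptor vector, context effects of co-occurring
  substructures are (partly) accounted for.

* *Student's method* (model-free): within one bioactivity set (one target),
  the pIC50 distribution of compounds containing a substructure is compared
  to that of compounds lacking it. Both groups must pass a Shapiro-Wilk
  normality gate (α = 0.05); if so, a two-tailed independent-samples t-test
  decides significance, and the sign of the mean difference assigns the
  beneficial/deleterious label. Substructures are treated as independent, so
  the two methods can legitimately disagree when effects ride on co-occurring
  substructures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bioactivity import BioactivityTable

__all__ = [
    "SubstructureContribution",
    "StudentResult",
    "predictive_contribution",
    "predictive_contribution_map",
    "students_method",
    "students_method_map",
    "classify_substructures",
]


@dataclass(frozen=True)
class SubstructureContribution:
    """Average model-estimated effect of one substructure on one target."""

    substructure_id: str
    target_id: str | None
    mean_delta: float
    sd_delta: float
    n_compounds: int
    total_count: float


@dataclass(frozen=True)
class StudentResult:
    """Distribution-comparison verdict for one substructure in one set."""

    substructure_id: str
    bioactivity_set: str
    n_present: int
    n_absent: int
    shapiro_p_present: float | None
    shapiro_p_absent: float | None
    t_p: float | None
    mean_difference: float | None
    assessed: bool
    label: str  # beneficial | deleterious | not significant | not assessed


def predictive_contribution(
    model,
    design_rows: pd.DataFrame,
    substructure: str,
    counts=None,
    target_id: str | None = None,
) -> SubstructureContribution:
    """Count-weighted mean prediction drop when a substructure is zeroed.

    ``model.predict`` must accept *raw* (unscaled) design rows and apply its
    own frozen preprocessing, so that zeroing a raw count is a well-defined
    virtual removal. ``counts`` defaults to the substructure's own column.
    Only rows with a positive count participate; Δ_i = ŷ(original) -
    ŷ(zeroed) and the reported mean is Σc_iΔ_i / Σc_i with an unweighted SD.
    """
    if substructure not in design_rows.columns:
        raise KeyError(f"substructure column {substructure!r} not in design")
    col_counts = (
        np.asarray(counts, dtype=float)
        if counts is not None
        else design_rows[substructure].to_numpy(dtype=float)
    )
    present = col_counts > 0
    if not present.any():
        raise ValueError(f"substructure {substructure!r} absent from all rows")

    rows = design_rows.loc[present]
    c = col_counts[present]
    zeroed = rows.copy()
    zeroed[substructure] = 0.0

    delta = np.asarray(model.predict(rows), dtype=float) - np.asarray(
        model.predict(zeroed), dtype=float
    )
    return SubstructureContribution(
        substructure_id=substructure,
        target_id=target_id,
        mean_delta=float(np.sum(c * delta) / np.sum(c)),
        sd_delta=float(delta.std(ddof=1)) if len(delta) > 1 else 0.0,
        n_compounds=int(present.sum()),
        total_count=float(c.sum()),
    )


def predictive_contribution_map(
    model,
    design: pd.DataFrame,
    substructures,
    target_id: str | None = None,
) -> list[SubstructureContribution]:
    """One contribution per substructure occurring in the (sub)design.

    ``substructures`` is a vocabulary object (with ``columns``) or an
    explicit list of fingerprint column names. When the design is indexed by
    (compound_id, target_id) pairs and ``target_id`` is given, rows are
    restricted to that target. Results are ordered by |mean Δ| descending,
    ties by identifier.
    """
    columns = getattr(substructures, "columns", substructures)
    rows = design
    if target_id is not None:
        if isinstance(design.index, pd.MultiIndex):
            if target_id not in design.index.get_level_values("target_id"):
                raise KeyError(f"target {target_id!r} not present in design")
            rows = design.xs(target_id, level="target_id", drop_level=False)
        else:
            raise KeyError("target selection requires a (compound, target)-indexed design")

    out = []
    for sub in columns:
        if sub in rows.columns and (rows[sub] > 0).any():
            out.append(predictive_contribution(model, rows, sub, target_id=target_id))
    out.sort(key=lambda contribution: (-abs(contribution.mean_delta), contribution.substructure_id))
    return out


def contribution_matrix(
    contributions_per_target: dict[str, list[SubstructureContribution]]
) -> pd.DataFrame:
    """Targets x substructures matrix of mean contributions (heatmap-ready)."""
    records = {
        target: {c.substructure_id: c.mean_delta for c in contribs}
        for target, contribs in contributions_per_target.items()
    }
    return pd.DataFrame.from_dict(records, orient="index")


def students_method(
    table: BioactivityTable,
    counts: pd.DataFrame,
    substructure: str,
    bioactivity_set: str,
    alpha: float = 0.05,
    min_group_size: int = 3,
    equal_var: bool = False,
) -> StudentResult:
    """Normality-gated t-test between present/absent pIC50 distributions.

    ``counts`` is indexed by compound id; ``bioactivity_set`` names the
    target whose pIC50 values form the set. Welch's unequal-variance t-test
    is used by default (``equal_var=True`` switches to the pooled-variance
    variant). Groups smaller than ``min_group_size`` or failing the
    Shapiro-Wilk gate yield "not assessed".
    """
    set_values = {
        cid: v for (cid, tid), v in table.entries.items() if tid == bioactivity_set
    }
    if not set_values:
        raise KeyError(f"unknown or empty bioactivity set {bioactivity_set!r}")
    if substructure not in counts.columns:
        raise KeyError(f"substructure column {substructure!r} not in counts")

    present_ids = set(counts.index[counts[substructure] > 0])
    a = np.array([v for cid, v in set_values.items() if cid in present_ids])
    b = np.array([v for cid, v in set_values.items() if cid not in present_ids])

    def _not_assessed(sp_a=None, sp_b=None) -> StudentResult:
        return StudentResult(
            substructure_id=substructure,
            bioactivity_set=bioactivity_set,
            n_present=len(a),
            n_absent=len(b),
            shapiro_p_present=sp_a,
            shapiro_p_absent=sp_b,
            t_p=None,
            mean_difference=float(a.mean() - b.mean()) if len(a) and len(b) else None,
            assessed=False,
            label="not assessed",
        )

    if len(a) < min_group_size or len(b) < min_group_size:
        return _not_assessed()

    sp_a = float(stats.shapiro(a).pvalue)
    sp_b = float(stats.shapiro(b).pvalue)
    if sp_a < alpha or sp_b < alpha:  # normality gate failed
        return _not_assessed(sp_a, sp_b)

    t_p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    diff = float(a.mean() - b.mean())
    if t_p < alpha:
        label = "beneficial" if diff > 0 else "deleterious"
    else:
        label = "not significant"
    return StudentResult(
        substructure_id=substructure,
        bioactivity_set=bioactivity_set,
        n_present=len(a),
        n_absent=len(b),
        shapiro_p_present=sp_a,
        shapiro_p_absent=sp_b,
        t_p=t_p,
        mean_difference=diff,
        assessed=True,
        label=label,
    )


def students_method_map(
    table: BioactivityTable,
    counts: pd.DataFrame,
    bioactivity_set: str,
    substructures=None,
    alpha: float = 0.05,
    adjust: str | None = None,
    **kwargs,
) -> list[StudentResult]:
    """Student's method over a whole vocabulary for one bioactivity set.

    ``adjust="bh"`` optionally applies a Benjamini-Hochberg correction to the
    assessed p-values before labeling (off by default; with small
    vocabularies no family-wise control is applied).
    """
    columns = getattr(substructures, "columns", substructures)
    if columns is None:
        columns = list(counts.columns)
    results = [
        students_method(table, counts, sub, bioactivity_set, alpha=alpha, **kwargs)
        for sub in columns
    ]
    if adjust == "bh":
        assessed = [r for r in results if r.assessed and r.t_p is not None]
        if assessed:
            order = np.argsort([r.t_p for r in assessed])
            m = len(assessed)
            adjusted = {}
            prev = 1.0
            for rank, idx in list(enumerate(order, start=1))[::-1]:
                p_adj = min(prev, assessed[idx].t_p * m / rank)
                adjusted[assessed[idx].substructure_id] = p_adj
                prev = p_adj
            results = [
                r
                if not r.assessed
                else StudentResult(
                    **{
                        **r.__dict__,
                        "t_p": adjusted[r.substructure_id],
                        "label": (
                            ("beneficial" if r.mean_difference > 0 else "deleterious")
                            if adjusted[r.substructure_id] < alpha
                            else "not significant"
                        ),
                    }
                )
                for r in results
            ]
    return results


def classify_substructures(
    results_set1: list[StudentResult],
    results_set2: list[StudentResult],
) -> pd.DataFrame:
    """Assign significant substructures to effect-direction x isoform bins.

    Bins are {increase, decrease} x {set-1 only, set-2 only, both}; a
    substructure significant on both sets with opposite signs is labeled
    "opposite". The returned frame also carries volcano-plot columns
    (mean difference, -log10 p, group size) for each set.
    """
    by_id_1 = {r.substructure_id: r for r in results_set1}
    by_id_2 = {r.substructure_id: r for r in results_set2}
    if set(by_id_1) != set(by_id_2):
        raise ValueError("both result sets must cover the same substructures")

    rows = []
    for sub in by_id_1:
        r1, r2 = by_id_1[sub], by_id_2[sub]
        sig1 = r1.label in ("beneficial", "deleterious")
        sig2 = r2.label in ("beneficial", "deleterious")
        if sig1 and sig2:
            if r1.label == r2.label:
                direction = "increase" if r1.label == "beneficial" else "decrease"
                bin_label = f"{direction} on both"
            else:
                bin_label = "opposite"
        elif sig1:
            direction = "increase" if r1.label == "beneficial" else "decrease"
            bin_label = f"{direction} on {r1.bioactivity_set} only"
        elif sig2:
            direction = "increase" if r2.label == "beneficial" else "decrease"
            bin_label = f"{direction} on {r2.bioactivity_set} only"
        else:
            bin_label = "not significant"
        rows.append(
            {
                "substructure_id": sub,
                "bin": bin_label,
                "label_set1": r1.label,
                "label_set2": r2.label,
                "mean_diff_set1": r1.mean_difference,
                "mean_diff_set2": r2.mean_difference,
                "neglog10_p_set1": -np.log10(r1.t_p) if r1.t_p else np.nan,
                "neglog10_p_set2": -np.log10(r2.t_p) if r2.t_p else np.nan,
                "n_present_set1": r1.n_present,
                "n_present_set2": r2.n_present,
            }
        )
    return pd.DataFrame(rows).set_index("substructure_id")
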