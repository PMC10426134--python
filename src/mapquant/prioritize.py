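"""Tumor-antigen prioritization from expression matrices.

The cascade mirrors a tumor-specific-antigen (TSA) discovery workflow:
peptides are discarded if unlocatable, then if expressed at or above the
presentation threshold (8.55 RPHM, the minimum expression giving > 5%
probability of generating a MAP) in tolerance-inducing cells (mTEC/DC),
then in peripheral normal tissues; survivors must be upregulated at least
fivefold in tumor versus normal and, when ribosome profiling is supplied,
show elongation reads.  High expression restricted to testis flags a
cancer-testis antigen (CTA) instead of discarding.

An L2 logistic regression on mTEC and DC RPHM (liblinear solver) scores
immunogenicity, evaluated by stratified shuffle splits (10 repeats, 20%
held out) with mean ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

RPHM_THRESHOLD = 8.55
FOLD_CHANGE = 5.0
PSEUDOCOUNT = 0.5


@dataclass
class SampleGroup:
    """Named set of samples with a cascade role."""

    name: str
    samples: list[str]
    role: str  # tolerance | normal | tumor | translation

    def __post_init__(self):
        if not self.samples:
            raise ValueError(f"group {self.name!r} has no members")
        if self.role not in ("tolerance", "normal", "tumor", "translation"):
            raise ValueError(f"unknown role {self.role!r} for group {self.name!r}")


def build_matrix(records, groups: list[SampleGroup], value: str = "rphm") -> pd.DataFrame:
    """Peptide x group grid of mean per-sample expression.

    `records` is an iterable of objects with .peptide/.sample and the value
    attribute (rphm or log_rphm).  A missing (peptide, sample) pair is an
    error rather than a silent zero.
    """
    rows = [
        {"peptide": r.peptide, "sample": r.sample, "value": getattr(r, value)}
        for r in records
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no expression records")
    wide = df.pivot_table(index="peptide", columns="sample", values="value", aggfunc="mean")
    out = {}
    for g in groups:
        missing = set(g.samples) - set(wide.columns)
        if missing:
            raise ValueError(f"group {g.name!r}: samples {sorted(missing)} have no records")
        sub = wide[g.samples]
        if sub.isna().any().any():
            bad = sub.index[sub.isna().any(axis=1)].tolist()
            raise ValueError(f"group {g.name!r}: missing records for peptides {bad}")
        out[g.name] = sub.mean(axis=1)
    return pd.DataFrame(out)


def threshold_filter(
    matrix: pd.DataFrame,
    groups: list[SampleGroup],
    role: str,
    threshold: float = RPHM_THRESHOLD,
    direction: str = "discard_if_ge",
    exempt_groups: set[str] = frozenset(),
) -> tuple[list[str], dict[str, str]]:
    """Discard peptides at/above threshold in any group of the given role.

    Returns (survivors, {peptide: offending group}).  Exempt groups (e.g.
    testis under the CTA exemption) are not checked.
    """
    role_groups = [g for g in groups if g.role == role and g.name not in exempt_groups]
    if not any(g.role == role for g in groups):
        raise ValueError(f"no groups with role {role!r}")
    if direction != "discard_if_ge":
        raise ValueError(f"unknown direction {direction!r}")
    survivors, discarded = [], {}
    for peptide in matrix.index:
        hit = next(
            (g.name for g in role_groups if matrix.at[peptide, g.name] >= threshold),
            None,
        )
        if hit is None:
            survivors.append(peptide)
        else:
            discarded[peptide] = hit
    return survivors, discarded


@dataclass
class TSACall:
    peptide: str
    passed_filters: list[str] = field(default_factory=list)
    is_tsa: bool = False
    is_cta: bool = False
    discarded_at: str | None = None
    fold_change: float | None = None
    ribo_reads: float | None = None


def tsa_cascade(
    matrix: pd.DataFrame,
    groups: list[SampleGroup],
    no_location: set[str] = frozenset(),
    ribo_counts: pd.Series | None = None,
    threshold: float = RPHM_THRESHOLD,
    fold_change: float = FOLD_CHANGE,
    pseudocount: float = PSEUDOCOUNT,
    cta_exemption: bool = True,
) -> list[TSACall]:
    """Ordered TSA filter cascade; each peptide records its drop stage.

    Stages: (1) drop peptides with no genomic location; (2) tolerance
    filter (mTEC/DC union); (3) normal-tissue filter, testis exempt when
    the CTA exemption is on (high testis expression flags CTA); (4) tumor
    vs normal fold change >= `fold_change` with a pseudocount denominator;
    (5) ribosome-profiling reads > 0 when supplied.
    """
    for role in ("tolerance", "normal", "tumor"):
        if not any(g.role == role for g in groups):
            raise ValueError(f"cascade requires a group with role {role!r}")
    tolerance = [g for g in groups if g.role == "tolerance"]
    normal = [g for g in groups if g.role == "normal"]
    tumor = [g for g in groups if g.role == "tumor"]
    testis_names = {g.name for g in normal if "testis" in g.name.lower()}
    exempt = testis_names if cta_exemption else set()

    calls = []
    for peptide in matrix.index:
        call = TSACall(peptide=peptide)
        calls.append(call)
        if peptide in no_location:
            call.discarded_at = "no_location"
            continue
        call.passed_filters.append("location")
        if any(matrix.at[peptide, g.name] >= threshold for g in tolerance):
            call.discarded_at = "tolerance"
            continue
        call.passed_filters.append("tolerance")
        offending = [
            g.name
            for g in normal
            if g.name not in exempt and matrix.at[peptide, g.name] >= threshold
        ]
        if offending:
            call.discarded_at = "normal"
            continue
        call.passed_filters.append("normal")
        if cta_exemption and any(
            matrix.at[peptide, name] >= threshold for name in testis_names
        ):
            call.is_cta = True
        tumor_mean = float(np.mean([matrix.at[peptide, g.name] for g in tumor]))
        # exempt (testis) groups stay out of the fold-change reference too:
        # a CTA's testis signal must not mask tumor upregulation
        fc_normal = [g for g in normal if g.name not in exempt] or normal
        normal_mean = float(np.mean([matrix.at[peptide, g.name] for g in fc_normal]))
        call.fold_change = tumor_mean / (normal_mean + pseudocount)
        if call.fold_change < fold_change:
            call.discarded_at = "fold_change"
            continue
        call.passed_filters.append("fold_change")
        if ribo_counts is not None:
            call.ribo_reads = float(ribo_counts.get(peptide, 0))
            if call.ribo_reads <= 0:
                call.discarded_at = "ribo"
                continue
            call.passed_filters.append("ribo")
        call.is_tsa = True
    return calls


def cascade_summary(calls: list[TSACall]) -> dict[str, int]:
    """Peptides remaining after each stage plus per-stage discard counts."""
    out = {"input": len(calls), "tsa": sum(c.is_tsa for c in calls)}
    for c in calls:
        if c.discarded_at:
            out[f"discarded_{c.discarded_at}"] = out.get(f"discarded_{c.discarded_at}", 0) + 1
    return out


def fit_immunogenicity(
    features: pd.DataFrame,
    labels,
    n_splits: int = 10,
    test_size: float = 0.2,
    random_state: int = 0,
) -> tuple[LogisticRegression, float, list[float]]:
    """Logistic regression on tolerance-cell expression features.

    Features are per-peptide mean RPHM in mTEC and DC groups; labels are
    immunogenic (1) / non-immunogenic (0).  Returns the model fitted on all
    data, the mean held-out ROC-AUC over stratified shuffle splits, and the
    per-split AUCs.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both immunogenic and non-immunogenic labels are required")
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_size, random_state=random_state
    )
    aucs = []
    for train, test in splitter.split(X, y):
        model = LogisticRegression(solver="liblinear")
        model.fit(X[train], y[train])
        aucs.append(roc_auc_score(y[test], model.predict_proba(X[test])[:, 1]))
    final = LogisticRegression(solver="liblinear").fit(X, y)
    return final, float(np.mean(aucs)), [float(a) for a in aucs]


def predict_immunogenicity(model: LogisticRegression, features: pd.DataFrame) -> np.ndarray:
    """Per-peptide probability of being immunogenic."""
    return model.predict_proba(np.asarray(features, dtype=float))[:, 1]
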