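"""Group-versus-control comparisons of the cleaned serology features.

Each case or parent group is compared to controls for each analyte, with
age at blood draw and sex as covariates: a linear model on the residual
scale for continuous analytes, a logistic model on serostatus for binarized
ones.  Tests are Wald and one-sided -- only increases relative to controls
are in the direction of the infection/inflammation hypothesis -- so a cell
whose effect goes the wrong way can never be significant, and is marked
"n/a" in the assembled table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import ANALYTES, ANTIBODIES, CONTROL, GROUPS
from .glm import DegenerateDesignError, fit_linear, fit_logistic

log = logging.getLogger(__name__)

NOMINAL_ALPHA = 0.05
SUGGESTIVE_ALPHA = 0.10


@dataclass
class AnalysisDataset:
    """Cleaned per-subject features ready for modelling.

    ``frame`` columns: subject_id, status, sex, age_at_draw, plus one
    feature column per analyte (residual for continuous analytes, 0/1
    serostatus for binarized ones).  ``feature_types`` maps analyte ->
    "continuous" | "binary".
    """

    frame: pd.DataFrame
    feature_types: dict

    def __post_init__(self) -> None:
        for a, t in self.feature_types.items():
            if t not in ("continuous", "binary"):
                raise ValueError(f"{a}: unknown feature type {t!r}")


def build_analysis_dataset(subjects, residuals, decisions) -> AnalysisDataset:
    """Assemble the modelling table from cleaning output and per-analyte
    bimodality decisions (binarizing where bimodal)."""
    from .mixture import binarize

    frame = subjects[["subject_id", "status", "sex", "age_at_draw"]].copy()
    merged = frame.merge(residuals, on="subject_id", how="left")
    types = {}
    for a in ANALYTES:
        d = decisions[a]
        if d.is_bimodal:
            frame[a] = binarize(merged[a].to_numpy(dtype=float), d)
            types[a] = "binary"
        else:
            frame[a] = merged[a].to_numpy(dtype=float)
            types[a] = "continuous"
    return AnalysisDataset(frame, types)


@dataclass
class ComparisonResult:
    analyte: str
    group: str
    beta: float
    se: float
    p_one_sided: float
    direction_expected: bool
    n_used: int
    status: str = "ok"        # ok | zero_cell | separation | degenerate

    @property
    def p_two_sided(self) -> float:
        return 2.0 * min(self.p_one_sided, 1.0 - self.p_one_sided)


def compare_group(
    dataset: AnalysisDataset,
    analyte: str,
    group: str,
) -> ComparisonResult:
    """Wald test of ``analyte ~ group + age + sex`` on group plus controls.

    One-sided p is the upper tail of the group coefficient (greater in the
    group than in controls).  Binary features with an empty seropositive or
    seronegative cell in either arm are reported as non-estimable instead of
    fitted.
    """
    f = dataset.frame
    sub = f[f["status"].isin([group, CONTROL])]
    feat = sub[analyte].to_numpy(dtype=float)
    ok = ~np.isnan(feat)
    sub = sub[ok]
    feat = feat[ok]
    n_group = int((sub["status"] == group).sum())
    n_ctrl = int((sub["status"] == CONTROL).sum())
    if n_group < 10 or n_ctrl < 10:
        raise ValueError(
            f"{analyte}/{group}: need >= 10 subjects per arm "
            f"(got {n_group} vs {n_ctrl})")
    is_grp = (sub["status"] == group).to_numpy(dtype=float)
    male = (sub["sex"] == "male").to_numpy(dtype=float)
    age = sub["age_at_draw"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), is_grp, age, male])

    if dataset.feature_types[analyte] == "binary":
        # zero cells make the group log-odds non-estimable
        for arm in (0.0, 1.0):
            vals = feat[is_grp == arm]
            if vals.min() == vals.max():
                return ComparisonResult(
                    analyte, group, float("nan"), float("nan"), float("nan"),
                    False, len(sub), status="zero_cell")
        try:
            fit = fit_logistic(X, feat)
        except DegenerateDesignError:
            return ComparisonResult(
                analyte, group, float("nan"), float("nan"), float("nan"),
                False, len(sub), status="degenerate")
        status = "separation" if "separation_suspected" in fit.flags else "ok"
    else:
        try:
            fit = fit_linear(X, feat)
        except DegenerateDesignError:
            return ComparisonResult(
                analyte, group, float("nan"), float("nan"), float("nan"),
                False, len(sub), status="degenerate")
        status = "ok"
    beta = float(fit.beta[1])
    return ComparisonResult(
        analyte=analyte, group=group, beta=beta, se=float(fit.se[1]),
        p_one_sided=fit.p_upper(1), direction_expected=beta > 0,
        n_used=len(sub), status=status)


def classify_cell(r: ComparisonResult) -> str:
    if r.status != "ok":
        return "non-estimable"
    if not r.direction_expected:
        return "n/a"
    if r.p_one_sided < NOMINAL_ALPHA:
        return "significant"
    if r.p_one_sided < SUGGESTIVE_ALPHA:
        return "suggestive"
    return "n.s."


def build_table(dataset: AnalysisDataset) -> pd.DataFrame:
    """The 6-analyte x 6-group comparison table (36 cells; the 30 antibody
    cells feed the enrichment statistics).  Missing groups yield absent
    cells with a logged warning."""
    rows = []
    present = set(dataset.frame["status"].unique())
    for a in ANALYTES:
        for g in GROUPS:
            if g not in present:
                log.warning("group %s absent; cell %s/%s skipped", g, a, g)
                continue
            r = compare_group(dataset, a, g)
            rows.append({
                "analyte": a, "group": g, "beta": r.beta, "se": r.se,
                "p_one_sided": r.p_one_sided,
                "direction_expected": r.direction_expected,
                "n_used": r.n_used, "status": r.status,
                "class": classify_cell(r),
            })
    return pd.DataFrame(rows)


def count_expected_direction(table: pd.DataFrame) -> int:
    """Antibody cells (CRP excluded) with a positive effect estimate."""
    ab = table[table["analyte"].isin(ANTIBODIES)]
    return int((ab["beta"] > 0).sum())


def count_nominally_significant(
    table: pd.DataFrame, alpha: float = NOMINAL_ALPHA
) -> int:
    """Antibody cells with one-sided p below ``alpha``."""
    ab = table[table["analyte"].isin(ANTIBODIES)]
    return int((ab["p_one_sided"] < alpha).sum())


def bonferroni_threshold(n_comparisons: int, alpha: float = 0.05) -> float:
    """Corrected per-test level for the full table (0.05/36 ~ 0.0014)."""
    return alpha / n_comparisons


# ---------------------------------------------------------------------------
# bundled reference comparison table

def load_reference_effects() -> pd.DataFrame:
    """The published effect table bundled with the package: per analyte and
    group, beta, SE and the printed one-sided p label (a number, "n.s.", or
    "n/a" for wrong-direction cells)."""
    with resources.files("serogx.datasets").joinpath(
            "reference_effects.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    df["p_numeric"] = pd.to_numeric(df["p_label"], errors="coerce")
    return df


def reference_direction_count(ref: pd.DataFrame | None = None) -> int:
    """Number of the 30 antibody cells in the reference table whose effect
    is in the expected (positive) direction."""
    ref = load_reference_effects() if ref is None else ref
    ab = ref[ref["analyte"].isin(ANTIBODIES)]
    return int((ab["beta"] > 0).sum())


def reference_significant_count(
    ref: pd.DataFrame | None = None, alpha: float = NOMINAL_ALPHA
) -> int:
    """Number of the 30 antibody cells with printed one-sided p < alpha."""
    ref = load_reference_effects() if ref is None else ref
    ab = ref[ref["analyte"].isin(ANTIBODIES)]
    return int((ab["p_numeric"] < alpha).sum())
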