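"""Permutation enrichment of one-sided antibody comparisons.

The null is built by breaking the link between diagnostic status and the
serology block while preserving everything else: the table is split
vertically into (antibody features + age at blood draw) and (status), and
the status sub-table is re-ordered uniformly at random *within each sex
stratum*.  A female's antibody measurements therefore always come from
another female, every status category keeps its sex composition, and the
age-antibody linkage is untouched.  For each permutation the full set of 30
antibody-by-group comparisons is re-fitted and two statistics recorded: the
number of nominally significant one-sided tests and the number of cells in
the expected (positive) direction.  Empirical p-values are k/N with ties
counted ("as or more extreme"); a (k+1)/(N+1) variant is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import ANTIBODIES, CONTROL, GROUPS
from .compare import AnalysisDataset
from .glm import DegenerateDesignError, fit_linear, fit_logistic

log = logging.getLogger(__name__)


def permute_linked(dataset: AnalysisDataset, seed) -> AnalysisDataset:
    """Return a copy of the dataset with status re-linked within sex.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Subjects
    missing sex are rejected.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    f = dataset.frame
    sex = f["sex"].to_numpy()
    if any(s not in ("male", "female") for s in np.unique(sex)):
        raise ValueError("every subject needs sex 'male' or 'female'")
    status = f["status"].to_numpy().copy()
    for s in ("male", "female"):
        idx = np.flatnonzero(sex == s)
        status[idx] = status[rng.permutation(idx)]
    out = f.copy()
    out["status"] = status
    return AnalysisDataset(out, dict(dataset.feature_types))


@dataclass
class PermutationEnrichment:
    observed_n_sig: int
    observed_n_dir: int
    alpha: float
    n_perm: int
    perm_n_sig: np.ndarray
    perm_n_dir: np.ndarray
    p_sig: float
    p_dir: float
    seed: int
    n_excluded: int = 0


def _antibody_counts(status, male, age, feats, types, alpha):
    """(n_sig, n_dir, ok) over the 30 antibody-by-group cells."""
    n_sig = 0
    n_dir = 0
    is_ctrl = status == CONTROL
    for a in ANTIBODIES:
        feat = feats[a]
        have = ~np.isnan(feat)
        for g in GROUPS:
            in_g = status == g
            mask = (in_g | is_ctrl) & have
            y = feat[mask]
            grp = in_g[mask].astype(float)
            X = np.column_stack(
                [np.ones(y.size), grp, age[mask], male[mask]])
            try:
                if types[a] == "binary":
                    for arm in (0.0, 1.0):
                        v = y[grp == arm]
                        if v.size == 0 or v.min() == v.max():
                            return 0, 0, False
                    fit = fit_logistic(X, y)
                    if not fit.converged:
                        return 0, 0, False
                else:
                    fit = fit_linear(X, y)
            except (DegenerateDesignError, np.linalg.LinAlgError):
                return 0, 0, False
            if fit.beta[1] > 0:
                n_dir += 1
            if fit.p_upper(1) < alpha:
                n_sig += 1
    return n_sig, n_dir, True


def _arrays(dataset: AnalysisDataset):
    f = dataset.frame
    return (
        f["status"].to_numpy(),
        (f["sex"] == "male").to_numpy(dtype=float),
        f["sex"].to_numpy(),
        f["age_at_draw"].to_numpy(dtype=float),
        {a: f[a].to_numpy(dtype=float) for a in ANTIBODIES if a in f.columns},
    )


def enrichment_test(
    dataset: AnalysisDataset,
    alpha: float = 0.05,
    n_perm: int = 3000,
    seed: int = 0,
    plus_one: bool = False,
) -> PermutationEnrichment:
    """Observed vs permuted counts of significant / expected-direction cells.

    A permutation replicate whose 30 cells cannot all be fitted (zero cell,
    separation, rank deficiency) is excluded and the denominator adjusted; a
    warning is emitted if more than 1% of replicates are lost.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm = {n_perm} must be >= 100")
    status, male, sex, age, feats = _arrays(dataset)
    missing = set(ANTIBODIES) - set(feats)
    if missing:
        raise ValueError(f"dataset lacks antibody features: {sorted(missing)}")
    obs_sig, obs_dir, ok = _antibody_counts(
        status, male, age, feats, dataset.feature_types, alpha)
    if not ok:
        raise RuntimeError("observed comparison table could not be fitted")

    rng = np.random.default_rng(seed)
    male_idx = np.flatnonzero(sex == "male")
    female_idx = np.flatnonzero(sex == "female")
    perm_sig = []
    perm_dir = []
    n_excluded = 0
    for _ in range(n_perm):
        st = status.copy()
        st[male_idx] = status[male_idx[rng.permutation(male_idx.size)]]
        st[female_idx] = status[female_idx[rng.permutation(female_idx.size)]]
        s, d, ok = _antibody_counts(
            st, male, age, feats, dataset.feature_types, alpha)
        if not ok:
            n_excluded += 1
            continue
        perm_sig.append(s)
        perm_dir.append(d)
    if n_excluded > 0.01 * n_perm:
        log.warning("%d of %d permutation replicates excluded (failed fits)",
                    n_excluded, n_perm)
    perm_sig = np.asarray(perm_sig)
    perm_dir = np.asarray(perm_dir)
    n_valid = perm_sig.size
    if n_valid == 0:
        raise RuntimeError("all permutation replicates failed")
    k_sig = int(np.sum(perm_sig >= obs_sig))
    k_dir = int(np.sum(perm_dir >= obs_dir))
    if plus_one:
        p_sig = (k_sig + 1) / (n_valid + 1)
        p_dir = (k_dir + 1) / (n_valid + 1)
    else:
        p_sig = k_sig / n_valid
        p_dir = k_dir / n_valid
    return PermutationEnrichment(
        observed_n_sig=obs_sig, observed_n_dir=obs_dir, alpha=alpha,
        n_perm=n_valid, perm_n_sig=perm_sig, perm_n_dir=perm_dir,
        p_sig=float(p_sig), p_dir=float(p_dir), seed=seed,
        n_excluded=n_excluded)
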