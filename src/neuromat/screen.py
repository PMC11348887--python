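"""Screen analytics: from per-well features to hit calls.

The normalization cascade follows the screen's design: per replicate, the
stimulated and unstimulated plates are paired (IEG fractions baseline-
subtracted, morphology averaged); each parameter is b-scored per plate
(two-way Tukey median polish, residuals scaled by 1.4826 × MAD); b-scores are
turned into library-wide robust z-scores per replicate; replicate z-vectors
are averaged; compounds with viability z < −2 are excluded; PCA on the
remaining compound × 6 z-matrix selects hits with PC1 above the threshold
(default 4), and the top-k (default 5) single-parameter scorers for neurite
length and double-IEG induction are added, excluding compounds already
selected by PCA.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScreenConfig
from .synth import MORPHOLOGY_FEATURES, PlateFeatureSet

__all__ = [
    "PARAMS",
    "ScreenResult",
    "ValidationResult",
    "pair_plates",
    "median_polish",
    "bscore",
    "robust_z",
    "zscore",
    "viability_filter",
    "pca_hits",
    "single_param_hits",
    "score_screen",
    "validation_score",
    "dose_response",
]

# the six maturity parameters, post-pairing
PARAMS = ("nucleus_area", "nucleus_roundness", "neurite_length", "n_segments",
          "induced_frac_fos", "induced_frac_egr1")

MAD_SCALE = 1.4826


# ---------------------------------------------------------------------------
# Plate pairing
# ---------------------------------------------------------------------------


def pair_plates(features: pd.DataFrame) -> pd.DataFrame:
    """Pair stimulated with unstimulated wells per replicate and plate.

    Induced IEG fractions are stimulated − unstimulated per well pair
    (negative values allowed); morphology parameters are averaged across the
    pair.  Viability is the unstimulated plate's nuclei count (depolarization
    itself can alter counts, so the unstressed plate is the cleaner proxy).
    Raises if any well address is present in one condition but not the other.
    """
    key = ["replicate", "plate", "well"]
    stim = features[features["condition"] == "stim"].set_index(key)
    unstim = features[features["condition"] == "unstim"].set_index(key)
    orphans = stim.index.symmetric_difference(unstim.index)
    if len(orphans):
        raise ValueError(
            f"unmatched well addresses between plate conditions: "
            f"{list(orphans[:5])}" + ("…" if len(orphans) > 5 else ""))
    unstim = unstim.loc[stim.index]
    out = pd.DataFrame(index=stim.index)
    out["compound_id"] = stim["compound_id"]
    out["row"] = stim["row"]
    out["col"] = stim["col"]
    for feat in MORPHOLOGY_FEATURES:
        out[feat] = (stim[feat].to_numpy() + unstim[feat].to_numpy()) / 2.0
    for frac in ("frac_fos", "frac_egr1", "frac_double"):
        out["induced_" + frac.removeprefix("frac_")] = (
            stim[frac].to_numpy() - unstim[frac].to_numpy())
    out = out.rename(columns={"induced_fos": "induced_frac_fos",
                              "induced_egr1": "induced_frac_egr1",
                              "induced_double": "induced_frac_double"})
    out["viability"] = unstim["nuclei_count"].to_numpy()
    return out.reset_index()


# ---------------------------------------------------------------------------
# b-score
# ---------------------------------------------------------------------------


def median_polish(matrix: np.ndarray, max_iter: int = 100,
                  tol: float = 1e-6) -> np.ndarray:
    """Residuals of Tukey's two-way median polish (NaN-tolerant).

    Alternately sweeps row and column medians (rows first), carrying the
    overall-effect term, until the largest absolute change of any effect in a
    sweep falls below ``tol`` or ``max_iter`` is reached.
    """
    r = np.array(matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("median polish needs a matrix of at least 2 × 2")
    overall = 0.0
    row_eff = np.zeros(r.shape[0])
    col_eff = np.zeros(r.shape[1])
    with warnings.catch_warnings():
        # all-NaN rows/columns (empty plate regions) are legal inputs
        warnings.filterwarnings("ignore", "All-NaN slice",
                                category=RuntimeWarning)
        for _ in range(max_iter):
            delta = 0.0
            rmed = np.nanmedian(r, axis=1)
            rmed = np.where(np.isnan(rmed), 0.0, rmed)
            r -= rmed[:, None]
            row_eff += rmed
            ce_med = np.nanmedian(col_eff)
            col_eff -= ce_med
            overall += ce_med
            delta = max(delta, np.max(np.abs(rmed)), abs(ce_med))

            cmed = np.nanmedian(r, axis=0)
            cmed = np.where(np.isnan(cmed), 0.0, cmed)
            r -= cmed[None, :]
            col_eff += cmed
            re_med = np.nanmedian(row_eff)
            row_eff -= re_med
            overall += re_med
            delta = max(delta, np.max(np.abs(cmed)), abs(re_med))
            if delta < tol:
                break
    return r


def bscore(plate_matrix: np.ndarray, max_iter: int = 100,
           tol: float = 1e-6) -> np.ndarray:
    """b-scores of one plate × one parameter.

    Median-polish residuals divided by 1.4826 × the median absolute residual;
    a zero MAD (e.g. a constant plate) yields all-zero b-scores.
    """
    resid = median_polish(plate_matrix, max_iter=max_iter, tol=tol)
    mad = np.nanmedian(np.abs(resid))
    if not np.isfinite(mad) or mad == 0.0:
        return np.where(np.isnan(resid), np.nan, 0.0)
    return resid / (MAD_SCALE * mad)


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------


def robust_z(values: np.ndarray, reference: np.ndarray,
             robust: bool = True) -> np.ndarray:
    """z-scores of ``values`` against a reference distribution.

    Robust (default): z = (x − median) / (1.4826 × MAD).  Classical:
    (x − mean) / SD.  Needs ≥ 3 finite reference values.
    """
    ref = np.asarray(reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < 3:
        raise ValueError("need at least 3 reference values")
    x = np.asarray(values, dtype=float)
    if robust:
        loc = np.median(ref)
        scale = MAD_SCALE * np.median(np.abs(ref - loc))
    else:
        loc = ref.mean()
        scale = ref.std(ddof=1)
    if scale == 0.0:
        return np.zeros_like(x)
    return (x - loc) / scale


def zscore(replicate_values: Sequence[np.ndarray],
           references: Optional[Sequence[np.ndarray]] = None,
           robust: bool = True) -> np.ndarray:
    """Per-replicate robust z-scores averaged across replicates.

    ``replicate_values`` is a sequence of per-replicate arrays (aligned by
    compound); each replicate is z-scored against its own reference (itself
    by default) and the z-vectors are averaged.
    """
    zs = []
    for i, vals in enumerate(replicate_values):
        ref = references[i] if references is not None else vals
        zs.append(robust_z(vals, ref, robust=robust))
    return np.mean(zs, axis=0)


def viability_filter(viability_z: pd.Series, threshold: float = -2.0):
    """Split compounds into (retained, excluded) by viability z.

    Exclusion is strict: z < threshold; a compound exactly at the threshold
    is retained.
    """
    excluded = viability_z.index[viability_z < threshold]
    retained = viability_z.index[~(viability_z < threshold)]
    return list(retained), list(excluded)


# ---------------------------------------------------------------------------
# PCA hit selection
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Normalized screen with PCA coordinates, clusters and hit calls."""

    zmatrix: pd.DataFrame              # compound × PARAMS (+ extras)
    pc_scores: pd.DataFrame            # compound × PC1..PC6
    loadings: pd.DataFrame             # PARAMS × PC1..PC6
    explained_variance: np.ndarray     # fractions, non-increasing
    cluster_labels: pd.Series          # per retained compound
    hits_pca: list
    hits_single_param: list = dc_field(default_factory=list)
    excluded_toxic: list = dc_field(default_factory=list)
    viability_z: Optional[pd.Series] = None
    degenerate_components: list = dc_field(default_factory=list)


def orient_components(loadings: np.ndarray, scores: np.ndarray,
                      fos_index: int):
    """Resolve eigenvector sign indeterminacy.

    PC1 is oriented so the FOS-fraction loading is positive; every other
    component so its largest-magnitude loading is positive.  Reported scores
    are therefore invariant to sign flips of the eigenvectors.
    """
    loadings = loadings.copy()
    scores = scores.copy()
    for j in range(loadings.shape[1]):
        if j == 0:
            flip = loadings[fos_index, 0] < 0
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        if flip:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores


def pca_hits(zmatrix: pd.DataFrame, cfg: Optional[ScreenConfig] = None,
             viability_z: Optional[pd.Series] = None) -> ScreenResult:
    """PCA on the compound × 6 z-matrix and hit calling at PC1 > threshold.

    The z-matrix is already on a common (z) scale, so components come from
    the covariance of the centered matrix with no further scaling.  Hits are
    compounds with PC1 strictly above ``cfg.pc1_threshold``.  Cluster labels:
    maturation-enhancing (PC1 > threshold), maturation-inhibiting
    (PC1 < −threshold), non-neuronal-proliferation (viability z > 2 with
    negative neurite z), other.
    """
    cfg = cfg or ScreenConfig()
    X = zmatrix[list(PARAMS)].to_numpy(dtype=float)
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need at least 7 compounds for a 6-parameter PCA")
    mu = X.mean(axis=0)
    C = np.cov(X - mu, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    scores = (X - mu) @ evecs
    evecs, scores = orient_components(evecs, scores,
                                      PARAMS.index("induced_frac_fos"))
    total = evals.sum()
    evr = evals / total if total > 0 else evals
    degenerate = [int(j) for j in range(len(evals))
                  if evals[j] < 1e-12 * max(total, 1.0)]

    comp_names = [f"PC{j + 1}" for j in range(len(evals))]
    pc_scores = pd.DataFrame(scores, index=zmatrix.index, columns=comp_names)
    loadings = pd.DataFrame(evecs, index=list(PARAMS), columns=comp_names)

    pc1 = pc_scores["PC1"]
    hits = list(zmatrix.index[pc1 > cfg.pc1_threshold])

    labels = pd.Series("other", index=zmatrix.index, dtype=object)
    labels[pc1 > cfg.pc1_threshold] = "maturation-enhancing"
    labels[pc1 < -cfg.pc1_threshold] = "maturation-inhibiting"
    if viability_z is not None:
        vz = viability_z.reindex(zmatrix.index)
        prolif = ((vz > 2) & (zmatrix["neurite_length"] < 0)
                  & (labels == "other"))
        labels[prolif] = "non-neuronal-proliferation"

    return ScreenResult(
        zmatrix=zmatrix, pc_scores=pc_scores, loadings=loadings,
        explained_variance=evr, cluster_labels=labels, hits_pca=hits,
        viability_z=viability_z, degenerate_components=degenerate)


def single_param_hits(zmatrix: pd.DataFrame,
                      params: Sequence[str] = ("neurite_length",
                                               "induced_frac_double"),
                      k: int = 5,
                      exclude: Iterable = ()) -> list:
    """Top-k compounds per single parameter, excluding ids already selected.

    Ties are broken by ascending compound id.  Returns the union across
    parameters, ordered by first appearance.
    """
    exclude = set(exclude)
    chosen: list = []
    for p in params:
        s = zmatrix[p].drop(labels=[i for i in zmatrix.index if i in exclude])
        if k > len(s):
            raise ValueError(f"k={k} exceeds the {len(s)} retained compounds")
        # stable sort on an id-sorted series → ties resolve by ascending id
        ranked = s.loc[sorted(s.index)].sort_values(
            ascending=False, kind="stable")
        for cid in ranked.index[:k]:
            if cid not in chosen:
                chosen.append(cid)
    return chosen


# ---------------------------------------------------------------------------
# Full screen scoring
# ---------------------------------------------------------------------------


def score_screen(plates: PlateFeatureSet | pd.DataFrame,
                 cfg: Optional[ScreenConfig] = None) -> ScreenResult:
    """Run the full cascade: pair → b-score → z-score → filter → PCA → hits."""
    cfg = cfg or ScreenConfig()
    features = plates.features if isinstance(plates, PlateFeatureSet) else plates
    paired = pair_plates(features)
    # the six maturity parameters (+ the double-IEG rescue parameter) go
    # through the sequential b-score → z-score cascade; viability is a plain
    # library z on nuclei counts — the exclusion rule needs no plate polish
    polish_params = PARAMS + ("induced_frac_double",)
    all_params = polish_params + ("viability",)

    rep_z: dict[str, list] = {p: [] for p in all_params}
    compounds = None
    for rep, rep_df in paired.groupby("replicate"):
        bcols = {}
        rows = []
        for plate, pdf in rep_df.groupby("plate"):
            nrow = int(pdf["row"].max()) + 1
            ncol = int(pdf["col"].max()) + 1
            for p in polish_params:
                m = np.full((nrow, ncol), np.nan)
                m[pdf["row"].to_numpy(), pdf["col"].to_numpy()] = \
                    pdf[p].to_numpy()
                b = bscore(m, max_iter=cfg.bscore_max_iter,
                           tol=cfg.bscore_tol)
                bcols.setdefault(p, []).append(
                    b[pdf["row"].to_numpy(), pdf["col"].to_numpy()])
            rows.append(pdf)
        rep_b = pd.concat(rows, ignore_index=True)
        for p in polish_params:
            rep_b[p + "_b"] = np.concatenate(bcols[p])
        rep_b["viability_b"] = rep_b["viability"]
        is_cmpd = rep_b["compound_id"] != "DMSO"
        cmpd = (rep_b[is_cmpd].groupby("compound_id")
                [[p + "_b" for p in all_params]].mean().sort_index())
        if compounds is None:
            compounds = cmpd.index
        for p in all_params:
            vals = cmpd[p + "_b"].to_numpy()
            rep_z[p].append(robust_z(vals, vals, robust=cfg.robust_z))

    zmatrix = pd.DataFrame(
        {p: np.mean(rep_z[p], axis=0) for p in all_params}, index=compounds)

    viability_z = zmatrix["viability"]
    retained, excluded = viability_filter(viability_z, cfg.viability_z)
    z_retained = zmatrix.loc[retained]

    result = pca_hits(z_retained, cfg, viability_z=viability_z.loc[retained])
    result.excluded_toxic = excluded
    result.hits_single_param = single_param_hits(
        z_retained, k=cfg.top_k, exclude=result.hits_pca)
    result.viability_z = viability_z
    return result


# ---------------------------------------------------------------------------
# Validation and dose-response
# ---------------------------------------------------------------------------

VALIDATION_PARAMS = ("nucleus_area", "nucleus_roundness", "neurite_length",
                     "induced_frac_double")


@dataclass
class ValidationResult:
    """DMSO-normalized composite scores of validation-stage compounds."""

    scores: pd.DataFrame        # compound_id, composite, per-parameter ratios
    ranking: list               # compound ids, descending composite


def validation_score(paired: pd.DataFrame) -> ValidationResult:
    """Composite validation score: mean of 4 DMSO-normalized parameters.

    Each of nucleus area, roundness, neurite length and the KCl-induced
    double FOS+/EGR-1+ fraction is divided by its DMSO mean on the same
    plate; the composite is the mean of the four ratios, so a DMSO-like well
    scores 1.0.  Requires ≥ 3 DMSO wells per plate.
    """
    rows = []
    for plate, pdf in paired.groupby("plate"):
        dmso = pdf[pdf["compound_id"] == "DMSO"]
        if len(dmso) < 3:
            raise ValueError(f"plate {plate} has fewer than 3 DMSO wells")
        ref = {p: dmso[p].mean() for p in VALIDATION_PARAMS}
        for cid, cdf in pdf[pdf["compound_id"] != "DMSO"].groupby(
                "compound_id"):
            ratios = {p: cdf[p].mean() / ref[p] for p in VALIDATION_PARAMS}
            rows.append({"compound_id": cid, "plate": plate, **ratios,
                         "composite": float(np.mean(list(ratios.values())))})
    scores = pd.DataFrame(rows)
    agg = (scores.groupby("compound_id")["composite"].mean()
           .sort_values(ascending=False, kind="stable"))
    return ValidationResult(scores=scores, ranking=list(agg.index))


def dose_response(composites: pd.DataFrame, seed: int = 0,
                  n_permutations: int = 10_000, alpha: float = 0.05) -> dict:
    """Dose-trend summary over a concentration series.

    ``composites`` has columns ``dose_nm`` and ``composite`` (one row per
    well).  Reports per-dose means, the Spearman rank correlation of the
    well-level composites with log10(dose), and a one-sided permutation
    p-value (exhaustive when the number of distinct permutations is ≤ 1e5,
    otherwise seeded Monte Carlo).  The ``dose_dependent`` flag is set when
    the correlation is positive with p < ``alpha``.
    """
    doses = composites["dose_nm"].to_numpy(dtype=float)
    y = composites["composite"].to_numpy(dtype=float)
    if len(np.unique(doses)) < 3:
        raise ValueError("need at least 3 dose levels")
    logd = np.log10(doses)
    rho = _spearman(logd, y)

    n = len(y)
    if math.factorial(n) <= 100_000:
        perms = itertools.permutations(range(n))
        count = total = 0
        for p in perms:
            total += 1
            if _spearman(logd, y[list(p)]) >= rho - 1e-12:
                count += 1
        pval = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 1  # the observed ordering
        for _ in range(n_permutations):
            if _spearman(logd, rng.permutation(y)) >= rho - 1e-12:
                count += 1
        pval = count / (n_permutations + 1)

    per_dose = (composites.groupby("dose_nm")["composite"].mean()
                .sort_index())
    return {
        "per_dose_mean": per_dose,
        "spearman_rho": float(rho),
        "p_value": float(pval),
        "dose_dependent": bool(rho > 0 and pval < alpha),
    }


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom > 0 else 0.0
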