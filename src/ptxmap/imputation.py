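"""Missing-genotype imputation: median, principal-component and LDA methods.

Genotype calls are coded per marker as consecutive class integers (AA = 0,
AB = 1, BB = 2 for biallelic configurations; four classes for ABxCD).  Three
imputers are provided:

* ``median`` — per-marker most frequent observed class;
* ``pc`` — rank-k SVD reconstruction of the class-coded, mean-filled,
  marker-centered matrix, rounded to the nearest valid class;
* ``lda`` — per-marker linear discriminant classification of the observed
  genotype classes on the population's first k SVD sample scores (the
  low-rank structure of a mapping population is linkage, so linked markers
  predict each other through the shared subspace).

Sample scores for the LDA route are computed once from the global SVD; a
shrinkage-regularised discriminant per marker then guards the k ~ n regime.
Markers whose discriminant cannot be fit (single observed class, degenerate
covariance) fall back to the median rule and are logged.

The masking cross-validation of :func:`cv_classification_error` hides a
fraction of the *observed* entries, imputes, and scores the misclassified
fraction — the criterion used to choose k.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import qc
from .formats_io import MISSING, GenotypeMatrix

METHODS = ("median", "pc", "lda")


@dataclasses.dataclass
class ImputeConfig:
    method: str = "lda"
    k: int = 80                 # components / linear discriminants
    mask_fraction: float = 0.05  # CV masking fraction
    reps: int = 10
    seed: int = 0

    def validate(self, n_samples: int | None = None,
                 n_markers: int | None = None) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if n_samples is not None and n_markers is not None:
            if self.k > min(n_samples, n_markers) - 1:
                raise ValueError(
                    f"k={self.k} exceeds min(n_samples, n_markers) - 1"
                )


def encode_genotypes(gm: GenotypeMatrix, stats: pd.DataFrame | None = None,
                     ) -> tuple[np.ndarray, list[list[str]], pd.Index]:
    """Class-code the call matrix: (codes with NaN, per-marker class lists,
    marker ids).  Classes are the configuration's valid genotypes in
    lexicographic order, so biallelic codes coincide with minor-allele
    dosage ordering AA < AB < BB."""
    if stats is None:
        stats = qc.marker_stats(gm)
    codes = np.full((gm.n_markers, gm.n_samples), np.nan)
    class_lists: list[list[str]] = []
    calls = gm.calls.to_numpy()
    parents = gm.parents.to_numpy()
    for i in range(gm.n_markers):
        cfg = stats["configuration"].iloc[i]
        if cfg in (qc.UNINFORMATIVE, qc.UNCLASSIFIABLE):
            class_lists.append([])
            continue
        classes = sorted(qc.expected_classes(parents[i, 0], parents[i, 1]))
        class_lists.append(classes)
        lut = {g: float(k) for k, g in enumerate(classes)}
        codes[i] = [lut.get(c, np.nan) for c in calls[i]]
    return codes, class_lists, gm.marker_ids


def decode_genotypes(codes: np.ndarray, class_lists: list[list[str]],
                     template: GenotypeMatrix) -> GenotypeMatrix:
    calls = np.full(codes.shape, MISSING, dtype="<U2")
    for i, classes in enumerate(class_lists):
        if not classes:
            continue
        row = codes[i]
        ok = np.isfinite(row)
        k = np.clip(np.rint(row[ok]).astype(int), 0, len(classes) - 1)
        calls[i, ok] = np.array(classes, dtype="<U2")[k]
    return GenotypeMatrix(
        markers=template.markers,
        calls=pd.DataFrame(calls, index=template.calls.index,
                           columns=template.calls.columns),
        parents=template.parents,
    )


def _row_modes(codes: np.ndarray, n_classes: np.ndarray) -> np.ndarray:
    """Most frequent observed class per marker (ties -> smaller class)."""
    m = codes.shape[0]
    out = np.full(m, np.nan)
    for i in range(m):
        row = codes[i]
        obs = row[np.isfinite(row)]
        if len(obs) == 0:
            continue
        counts = np.bincount(obs.astype(int), minlength=max(int(n_classes[i]), 1))
        out[i] = float(np.argmax(counts))
    return out


def _svd_scores(filled: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Sample scores (n x k) of the marker-centered matrix (samples x
    markers)."""
    x = filled.T  # samples x markers
    x = x - x.mean(axis=0, keepdims=True)
    k = min(k, min(x.shape) - 1)
    if k >= min(x.shape) - 1 or min(x.shape) <= 200:
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        return u[:, :k] * s[:k]
    from sklearn.decomposition import TruncatedSVD

    svd = TruncatedSVD(n_components=k, random_state=seed)
    return svd.fit_transform(x)


def impute_codes(codes: np.ndarray, class_lists: list[list[str]],
                 config: ImputeConfig) -> tuple[np.ndarray, list[int]]:
    """Impute a class-coded matrix; returns (completed codes, fallback rows).

    Observed entries are never altered.  Markers with no observed entries
    cannot be imputed and stay missing (the caller drops and reports them).
    """
    config.validate()
    codes = np.asarray(codes, dtype=float)
    m, n = codes.shape
    n_classes = np.array([max(len(c), 1) for c in class_lists])
    observed = np.isfinite(codes)
    modes = _row_modes(codes, n_classes)
    out = codes.copy()
    fallback_rows: list[int] = []

    if config.method == "median":
        fill = np.broadcast_to(modes[:, None], codes.shape)
        out[~observed] = fill[~observed]
        return out, fallback_rows

    row_mean = np.where(observed, codes, 0.0).sum(axis=1) / np.maximum(
        observed.sum(axis=1), 1)
    filled = np.where(observed, codes, row_mean[:, None])

    if config.method == "pc":
        k = min(config.k, min(m, n) - 1)
        x = filled.T - filled.T.mean(axis=0, keepdims=True)
        center = filled.T.mean(axis=0, keepdims=True)
        if k >= min(x.shape):
            recon = x
        else:
            u, s, vt = np.linalg.svd(x, full_matrices=False)
            recon = (u[:, :k] * s[:k]) @ vt[:k]
        recon = (recon + center).T
        vals = np.clip(np.rint(recon), 0, (n_classes - 1)[:, None])
        out[~observed] = vals[~observed]
        still = ~np.isfinite(out)
        out[still] = np.broadcast_to(modes[:, None], out.shape)[still]
        return out, fallback_rows

    # lda
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    scores = _svd_scores(filled, config.k, config.seed)
    for i in range(m):
        miss = ~observed[i]
        if not miss.any():
            continue
        obs_idx = np.flatnonzero(observed[i])
        y = codes[i, obs_idx].astype(int)
        if len(obs_idx) == 0:
            continue  # nothing observed; handled by caller
        if len(np.unique(y)) < 2 or len(obs_idx) <= len(np.unique(y)):
            out[i, miss] = modes[i]
            fallback_rows.append(i)
            continue
        try:
            # a small fixed ridge on the pooled covariance guards the k ~ n
            # regime; Ledoit-Wolf shrinkage overshrinks on linkage structure
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.02)
            clf.fit(scores[obs_idx], y)
            out[i, miss] = clf.predict(scores[miss]).astype(float)
        except Exception:
            out[i, miss] = modes[i]
            fallback_rows.append(i)
    return out, fallback_rows


def impute(gm: GenotypeMatrix, config: ImputeConfig,
           stats: pd.DataFrame | None = None,
           ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Impute all missing calls; returns (completed matrix, report).

    Markers that cannot be imputed (all calls missing, or unclassifiable
    configuration) are dropped and listed in the report.
    """
    if stats is None:
        stats = qc.marker_stats(gm)
    codes, class_lists, ids = encode_genotypes(gm, stats)
    observed = np.isfinite(codes)
    dead = ~observed.any(axis=1)
    unclass = np.array([len(c) == 0 for c in class_lists])
    drop = dead | unclass
    report_rows = [
        (str(ids[i]), "all_missing" if dead[i] else "unclassifiable")
        for i in np.flatnonzero(drop)
    ]
    keep = ~drop
    kept_codes = codes[keep]
    kept_classes = [c for c, k in zip(class_lists, keep) if k]
    completed, fb = impute_codes(kept_codes, kept_classes, config)
    for i in fb:
        report_rows.append((str(ids[np.flatnonzero(keep)[i]]), "lda_fallback"))
    kept_ids = ids[keep]
    template = gm.subset(kept_ids)
    new_gm = decode_genotypes(completed, kept_classes, template)
    report = pd.DataFrame(report_rows, columns=["marker_id", "reason"])
    return new_gm, report


def cv_classification_error(gm_or_codes, config: ImputeConfig,
                            class_lists: list[list[str]] | None = None,
                            ) -> float:
    """Masking cross-validation of one imputation configuration.

    Masks ``mask_fraction`` of the observed entries uniformly at random,
    imputes, and returns the misclassified fraction averaged over
    ``config.reps`` repetitions; deterministic given ``config.seed``.
    """
    if config.mask_fraction <= 0:
        raise ValueError("mask_fraction must be positive")
    if isinstance(gm_or_codes, GenotypeMatrix):
        codes, class_lists, _ = encode_genotypes(gm_or_codes)
    else:
        codes = np.asarray(gm_or_codes, dtype=float)
        if class_lists is None:
            raise ValueError("class_lists required with a raw code matrix")
    keep = np.isfinite(codes).any(axis=1) & np.array(
        [len(c) > 0 for c in class_lists])
    codes = codes[keep]
    class_lists = [c for c, k in zip(class_lists, keep) if k]
    rng = np.random.default_rng(config.seed)
    observed = np.isfinite(codes)
    obs_idx = np.argwhere(observed)
    errors = []
    for _ in range(config.reps):
        n_mask = max(1, int(round(config.mask_fraction * len(obs_idx))))
        pick = rng.choice(len(obs_idx), size=n_mask, replace=False)
        mask = obs_idx[pick]
        masked = codes.copy()
        masked[mask[:, 0], mask[:, 1]] = np.nan
        completed, _ = impute_codes(masked, class_lists, config)
        truth = codes[mask[:, 0], mask[:, 1]]
        pred = completed[mask[:, 0], mask[:, 1]]
        ok = np.isfinite(pred)
        if not ok.any():
            warnings.warn("no maskable entries imputed", stacklevel=2)
            continue
        errors.append(float((pred[ok] != truth[ok]).mean()))
    return float(np.mean(errors))


def cv_error_table(gm: GenotypeMatrix, k_grid=(5, 20, 80),
                   methods=METHODS, mask_fraction: float = 0.05,
                   reps: int = 3, seed: int = 0) -> pd.DataFrame:
    """Classification-error sweep over methods and component counts."""
    codes, class_lists, _ = encode_genotypes(gm)
    rows = []
    for method in methods:
        grid = [0] if method == "median" else k_grid
        for k in grid:
            cfg = ImputeConfig(method=method, k=max(k, 1),
                               mask_fraction=mask_fraction, reps=reps,
                               seed=seed)
            err = cv_classification_error(codes, cfg, class_lists)
            rows.append((method, k, err))
    return pd.DataFrame(rows, columns=["method", "k", "classification_error"])
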