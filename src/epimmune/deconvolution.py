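"""Reference-based cell-type deconvolution of bulk methylomes.

A bulk tumor methylome is modeled as a convex combination of cell-type mean
β profiles over a panel of signature CpGs: b ≈ R·f with f ≥ 0 and Σf = 1.
Ten cell types are estimated by default in this pipeline: Fibroblasts,
Neutrophils, CD4+ T, CD8+ T, Treg, CD14 (macrophages), CD19 (B cells),
CD56 (NK cells), Eosinophils, and Cancer cells.

Two solvers are provided:

* ``constrained_ls`` (default) — non-negative least squares with the
  sum-to-one constraint imposed inside the solver as a heavily weighted
  equality row of the augmented system; deterministic with a unique,
  testable optimum.
* ``nu_svr`` — ν-support-vector regression with a linear kernel over
  ν ∈ {0.25, 0.5, 0.75} (lowest reconstruction RMSE wins), negative
  coefficients clipped to zero and renormalized, in the spirit of
  CIBERSORT-style estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.svm import NuSVR

from .containers import BetaMatrix, CellTypeReference, PairedDesign

__all__ = [
    "intersect_reference",
    "MethylDeconvolver",
    "deconvolve",
    "DeconvolutionResult",
    "fraction_change",
]

#: minimum probes-per-cell-type ratio for an identifiable problem
_MIN_PROBES_PER_TYPE = 10


def intersect_reference(reference: CellTypeReference, beta: BetaMatrix) -> CellTypeReference:
    """Restrict the reference to signature probes present in the data.

    Raises when fewer than 10 × (number of cell types) probes remain, which
    would leave the mixture under-determined in practice.
    """
    shared = reference.probe_ids.intersection(beta.probe_ids)
    k = reference.profiles.shape[1]
    if len(shared) < _MIN_PROBES_PER_TYPE * k:
        raise ValueError(
            f"only {len(shared)} reference probes overlap the data; "
            f"need at least {_MIN_PROBES_PER_TYPE * k} for {k} cell types"
        )
    # preserve reference probe order
    keep = reference.probe_ids[reference.probe_ids.isin(shared)]
    return CellTypeReference(reference.profiles.loc[keep])


class MethylDeconvolver(TransformerMixin, BaseEstimator):
    """Scikit-learn style estimator for reference-based fraction estimation.

    Parameters
    ----------
    method : {"constrained_ls", "nu_svr"}
        Solver; see module docstring.
    sum_weight : float
        Weight of the sum-to-one equality row in the augmented NNLS system
        (constrained_ls only).
    nus : tuple of float
        ν grid searched by the SVR solver.

    Attributes
    ----------
    reference_ : DataFrame
        Probe × cell-type profile matrix seen during :meth:`fit`.
    cell_types_ : Index
        Cell-type names, the column order of transform outputs.
    """

    def __init__(self, method: str = "constrained_ls", sum_weight: float = 1e4, nus=(0.25, 0.5, 0.75)):
        self.method = method
        self.sum_weight = sum_weight
        self.nus = nus

    def fit(self, X, y=None):
        """Store the cell-type reference profiles (probe × cell type)."""
        if isinstance(X, CellTypeReference):
            X = X.profiles
        X = pd.DataFrame(X)
        if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
            raise ValueError("reference profile matrix is column-rank deficient")
        if self.method not in ("constrained_ls", "nu_svr"):
            raise ValueError(f"unknown method {self.method!r}")
        self.reference_ = X
        self.cell_types_ = X.columns
        return self

    def _solve_one(self, b: np.ndarray) -> tuple[np.ndarray, float]:
        R = self.reference_.to_numpy(dtype=float)
        if self.method == "constrained_ls":
            A = np.vstack([R, np.full((1, R.shape[1]), self.sum_weight)])
            rhs = np.concatenate([b, [self.sum_weight]])
            f, _ = nnls(A, rhs)
        else:
            best = None
            for nu in self.nus:
                svr = NuSVR(kernel="linear", nu=nu, C=1.0)
                svr.fit(R, b)
                coef = np.asarray(svr.coef_).ravel()
                rmse = float(np.sqrt(np.mean((R @ coef - b) ** 2)))
                if best is None or rmse < best[1]:
                    best = (coef, rmse)
            f = np.clip(best[0], 0.0, None)
        total = f.sum()
        if total <= 0:
            f = np.full_like(f, 1.0 / len(f))
        else:
            f = f / total
        resid = float(np.linalg.norm(R @ f - b))
        return f, resid

    def transform(self, X) -> pd.DataFrame:
        """Estimate fractions for each sample (columns of a probe × sample β
        matrix aligned to the fitted reference probes)."""
        if isinstance(X, BetaMatrix):
            X = X.values
        X = pd.DataFrame(X)
        missing = self.reference_.index.difference(X.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} reference probes absent from the input; intersect first"
            )
        B = X.loc[self.reference_.index].to_numpy(dtype=float)
        fracs = np.empty((B.shape[1], self.reference_.shape[1]))
        resid = np.empty(B.shape[1])
        for j in range(B.shape[1]):
            fracs[j], resid[j] = self._solve_one(B[:, j])
        out = pd.DataFrame(fracs, index=X.columns, columns=self.cell_types_)
        self.residual_norms_ = pd.Series(resid, index=X.columns, name="residual_norm")
        return out


@dataclass
class DeconvolutionResult:
    """Estimated sample × cell-type fractions with per-sample residual norms."""

    fractions: pd.DataFrame
    residual_norms: pd.Series
    method: str

    def __post_init__(self):
        if (self.fractions.to_numpy() < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("fraction rows must sum to 1 within 1e-6")


def deconvolve(
    beta: BetaMatrix | pd.DataFrame,
    reference: CellTypeReference,
    method: str = "constrained_ls",
) -> DeconvolutionResult:
    """Estimate cell-type fractions for every sample of ``beta``.

    The reference must already be intersected with the data
    (see :func:`intersect_reference`).
    """
    est = MethylDeconvolver(method=method).fit(reference)
    fractions = est.transform(beta)
    return DeconvolutionResult(fractions, est.residual_norms_, method)


def fraction_change(result: DeconvolutionResult, design: PairedDesign) -> dict:
    """Paired per-participant fraction changes.

    Returns a dict with ``absolute`` (on − base) and ``relative``
    ((on − base)/base; missing where base = 0) participant × cell-type
    frames, plus ``cohort_mean_relative`` per cell type.
    """
    base = result.fractions.loc[design.baseline_samples].to_numpy()
    on = result.fractions.loc[design.on_treatment_samples].to_numpy()
    idx = pd.Index(design.participants, name="participant")
    absolute = pd.DataFrame(on - base, index=idx, columns=result.fractions.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(base == 0, np.nan, (on - base) / base)
    relative = pd.DataFrame(rel, index=idx, columns=result.fractions.columns)
    return {
        "absolute": absolute,
        "relative": relative,
        "cohort_mean_relative": relative.mean(axis=0, skipna=True),
    }
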