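"""Spatial-block and leave-one-dataset-out cross-validation.

Random train/test splits leak information through spatial autocorrelation,
so model assessment tiles the study area into contiguous blocks and holds
out whole blocks at a time.  Scoring is the predictive log-likelihood of
the held-out data under the plug-in (MAP) state from the training fit:
for presence-only data the point-process log-density restricted to the
held-out blocks (quadrature subset included), for presence-absence and
count records their observation-model log-likelihood.  Leave-one-dataset-
out refits the model without each dataset in turn and scores that dataset
the same way — a direct check of cross-dataset consistency in an
integrated model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_io import OccurrenceDataset
from .errors import SDMFuseError
from .geometry import IntegrationScheme, SpatialDomain
from .inference import FitOptions, fit
from .model import count_loglik, pa_loglik


@dataclass(frozen=True)
class BlockAssignment:
    """Deterministic tiling of the domain into blocks grouped into folds."""

    k_x: int
    k_y: int
    n_folds: int
    seed: int
    bounds: tuple  # (xmin, ymin, xmax, ymax)
    block_fold: np.ndarray  # (k_x*k_y,) fold id, 0-based

    def block_of(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        bx = np.clip(((x - xmin) / (xmax - xmin) * self.k_x).astype(int), 0, self.k_x - 1)
        by = np.clip(((y - ymin) / (ymax - ymin) * self.k_y).astype(int), 0, self.k_y - 1)
        return by * self.k_x + bx

    def fold_of(self, x, y) -> np.ndarray:
        return self.block_fold[self.block_of(x, y)]

    def to_frame(self, x, y) -> pd.DataFrame:
        b = self.block_of(x, y)
        return pd.DataFrame({"x": x, "y": y, "block": b, "fold": self.block_fold[b]})


@dataclass(frozen=True)
class CVReport:
    """Per-fold (or per-dataset) predictive log-scores and their mean."""

    scores: pd.DataFrame  # columns: label, log_score, n_heldout, note
    aggregate: float

    def to_csv(self, path) -> None:
        out = self.scores.copy()
        out.loc[len(out)] = ["aggregate", self.aggregate, int(out["n_heldout"].sum()), ""]
        out.to_csv(path, index=False)


def assign_blocks(
    records_xy: np.ndarray,
    domain: SpatialDomain,
    k_x: int,
    k_y: int,
    n_folds: int,
    seed: int,
) -> BlockAssignment:
    """Tile the domain's bounding box into k_x × k_y blocks and deal the
    blocks to folds by a seeded permutation, balanced on block count."""
    if n_folds < 2 or k_x * k_y < n_folds:
        raise SDMFuseError("too-few-blocks", f"{k_x * k_y} blocks for {n_folds} folds")
    records_xy = np.atleast_2d(np.asarray(records_xy, dtype=float))
    bounds = domain.bounds
    n_blocks = k_x * k_y
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_blocks)
    block_fold = np.empty(n_blocks, dtype=int)
    block_fold[perm] = np.arange(n_blocks) % n_folds  # round-robin over permuted blocks
    assignment = BlockAssignment(
        k_x=k_x, k_y=k_y, n_folds=n_folds, seed=seed, bounds=bounds, block_fold=block_fold
    )
    if len(records_xy):
        occupied = np.unique(assignment.block_of(records_xy[:, 0], records_xy[:, 1]))
        if occupied.size < n_folds:
            raise SDMFuseError(
                "too-few-blocks", f"only {occupied.size} nonempty blocks for {n_folds} folds"
            )
    return assignment


def _subset_scheme(scheme: IntegrationScheme, keep: np.ndarray) -> IntegrationScheme | None:
    if not keep.any():
        return None
    return IntegrationScheme(points=scheme.points[keep], weights=scheme.weights[keep])


def _score_dataset(
    ds: OccurrenceDataset, result, scheme: IntegrationScheme | None
) -> float:
    """Plug-in predictive log-likelihood of a dataset under a fitted state."""
    jm = result.model
    state = result.state
    if ds.process == "presence_only":
        eta_pts = (
            jm.linear_predictor(state, ds.xy, with_bias=True) if len(ds) else np.zeros(0)
        )
        eta_quad = jm.linear_predictor(state, scheme.points, with_bias=True)
        return float(eta_pts.sum() - scheme.weights @ np.exp(eta_quad))
    if ds.process == "presence_absence":
        return pa_loglik(ds, state, jm.spec, jm.covariates, jm.shared_field)
    return count_loglik(ds, state, jm.spec, jm.covariates, jm.shared_field)


def spatial_block_cv(
    spec,
    datasets,
    priors,
    scheme,
    covariates,
    assignment: BlockAssignment,
    options: FitOptions = FitOptions(),
    shared_field=None,
    bias_field=None,
) -> CVReport:
    """K-fold spatial-block CV of the joint model.

    Each fold is fit on the remaining blocks (presence-only quadrature
    restricted to the training area) and scored on its held-out blocks.
    Folds with no held-out data are skipped with a note.
    """
    quad_fold = assignment.fold_of(scheme.points[:, 0], scheme.points[:, 1])
    ds_folds = [assignment.fold_of(d.records["x"], d.records["y"]) for d in datasets]
    rows = []
    for k in range(assignment.n_folds):
        train, test, n_test = [], [], 0
        for d, folds in zip(datasets, ds_folds):
            tr = d.subset(folds != k)
            te = d.subset(folds == k)
            if len(tr):
                train.append(tr)
            if len(te):
                test.append(te)
                n_test += len(te)
        test_quad = _subset_scheme(scheme, quad_fold == k)
        has_po_test = any(d.process == "presence_only" for d in test)
        if not test or (has_po_test and test_quad is None):
            rows.append({"label": f"fold_{k}", "log_score": np.nan, "n_heldout": 0,
                         "note": "skipped: no held-out data"})
            continue
        train_quad = _subset_scheme(scheme, quad_fold != k)
        result = fit(
            spec, train, priors, train_quad, covariates, options,
            shared_field=shared_field, bias_field=bias_field,
        )
        score = sum(
            _score_dataset(d, result, test_quad if d.process == "presence_only" else None)
            for d in test
        )
        rows.append({"label": f"fold_{k}", "log_score": float(score),
                     "n_heldout": int(n_test), "note": ""})
    frame = pd.DataFrame(rows)
    ok = frame["log_score"].notna()
    if not ok.any():
        raise SDMFuseError("too-few-blocks", "every fold was empty")
    agg = float(
        np.average(frame.loc[ok, "log_score"], weights=frame.loc[ok, "n_heldout"])
    )
    return CVReport(scores=frame, aggregate=agg)


def leave_one_dataset_out(
    spec,
    datasets,
    priors,
    scheme,
    covariates,
    options: FitOptions = FitOptions(),
    shared_field=None,
    bias_field=None,
) -> CVReport:
    """Refit without each dataset in turn; score the left-out dataset by
    its observation-model predictive log-likelihood."""
    if len(datasets) < 2:
        raise SDMFuseError("need-multiple-datasets", "leave-one-dataset-out needs >= 2")
    rows = []
    for i, held in enumerate(datasets):
        train = [d for j, d in enumerate(datasets) if j != i]
        result = fit(
            spec, train, priors, scheme, covariates, options,
            shared_field=shared_field, bias_field=bias_field,
        )
        score = _score_dataset(
            held, result, scheme if held.process == "presence_only" else None
        )
        rows.append({"label": held.name, "log_score": float(score),
                     "n_heldout": len(held), "note": ""})
    frame = pd.DataFrame(rows)
    agg = float(np.average(frame["log_score"], weights=frame["n_heldout"]))
    return CVReport(scores=frame, aggregate=agg)
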