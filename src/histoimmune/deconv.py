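"""Cell-composition deconvolution trained on simulated pseudo-bulk mixtures.

Pseudo-bulk samples are built by aggregating single-cell profiles drawn at
known (Dirichlet-sampled) proportions; an ensemble of three multilayer
perceptrons of increasing capacity — (256), (512, 128) and (512, 256, 64)
hidden units with dropout 0.0 / 0.2 / 0.4 — maps normalized expression to a
simplex of cell-type fractions via a softmax head.  The ensemble prediction
is the mean of member outputs, renormalized to the simplex.  Agreement with
ground truth is scored with the Pearson correlation coefficient, per sample
(across types) and per type (across samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .nn import MLP, AdamW, CosineAnnealing, Tensor

__all__ = [
    "PseudoBulkSample",
    "DeconvolutionEnsemble",
    "sample_fractions",
    "make_pseudobulk",
    "simulate_pseudobulk_dataset",
    "train_ensemble",
    "predict_fractions",
    "pcc_eval",
]

_SIMPLEX_TOL = 1e-6


def _check_simplex(f: np.ndarray, tol: float = _SIMPLEX_TOL) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f < -tol) or abs(f.sum() - 1.0) > tol:
        raise ValueError("fractions must be non-negative and sum to 1")
    return np.clip(f, 0.0, None)


@dataclass
class PseudoBulkSample:
    """One simulated bulk profile with its realized ground-truth composition."""

    expression: np.ndarray  # (G,) log1p CPM
    true_fractions: np.ndarray  # (T,) realized multinomial composition
    n_cells_used: int


def sample_fractions(n_types: int, alpha=1.0, seed: int = 0) -> np.ndarray:
    """Dirichlet(alpha) draw on the T-simplex."""
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n_types,))
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(alpha)


def make_pseudobulk(
    cells: ad.AnnData,
    fractions: np.ndarray,
    n_cells: int = 500,
    seed: int = 0,
    cell_types: list[str] | None = None,
) -> PseudoBulkSample:
    """Aggregate sampled single-cell profiles at given proportions.

    Per-type cell counts are a multinomial draw at ``fractions``; cells are
    sampled with replacement within each type, their raw count vectors are
    summed, and the sum is normalized to counts-per-million then log1p.
    ``true_fractions`` records the realized multinomial composition — what
    the mixture actually contains — not the Dirichlet parameter.
    """
    fractions = _check_simplex(fractions)
    if cell_types is None:
        cell_types = sorted(cells.obs["cell_type"].unique())
    if len(fractions) != len(cell_types):
        raise ValueError("one fraction per cell type required")
    if n_cells < len(cell_types):
        raise ValueError("n_cells must be at least the number of types")
    rng = np.random.default_rng(seed)
    counts_per_type = rng.multinomial(n_cells, fractions / fractions.sum())
    x = cells.X.toarray() if hasattr(cells.X, "toarray") else np.asarray(cells.X)
    labels = cells.obs["cell_type"].to_numpy()
    total = np.zeros(cells.n_vars, dtype=np.float64)
    for t, ct in enumerate(cell_types):
        if counts_per_type[t] == 0:
            continue
        pool = np.flatnonzero(labels == ct)
        if pool.size == 0:
            raise ValueError(f"no cells available for type {ct!r}")
        chosen = rng.choice(pool, size=counts_per_type[t], replace=True)
        total += x[chosen].sum(axis=0)
    cpm = total * (1e6 / total.sum())
    return PseudoBulkSample(
        expression=np.log1p(cpm),
        true_fractions=counts_per_type / n_cells,
        n_cells_used=int(n_cells),
    )


def simulate_pseudobulk_dataset(
    cells: ad.AnnData,
    n_samples: int,
    n_cells: int = 500,
    alpha=1.0,
    seed: int = 0,
    cell_types: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Simulate a pseudo-bulk design matrix X (n, G) and fractions F (n, T)."""
    if cells.n_obs == 0:
        raise ValueError("cell set is empty")
    if cell_types is None:
        cell_types = sorted(cells.obs["cell_type"].unique())
    rng = np.random.default_rng(seed)
    x = cells.X.toarray() if hasattr(cells.X, "toarray") else np.asarray(cells.X)
    labels = cells.obs["cell_type"].to_numpy()
    pools = {ct: np.flatnonzero(labels == ct) for ct in cell_types}
    for ct, pool in pools.items():
        if pool.size == 0:
            raise ValueError(f"no cells available for type {ct!r}")
    alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), (len(cell_types),))
    X = np.empty((n_samples, cells.n_vars), dtype=np.float32)
    F = np.empty((n_samples, len(cell_types)), dtype=np.float64)
    for i in range(n_samples):
        frac = rng.dirichlet(alpha_vec)
        per_type = rng.multinomial(n_cells, frac)
        total = np.zeros(cells.n_vars, dtype=np.float64)
        for t, ct in enumerate(cell_types):
            if per_type[t]:
                total += x[rng.choice(pools[ct], size=per_type[t], replace=True)].sum(axis=0)
        X[i] = np.log1p(total * (1e6 / total.sum()))
        F[i] = per_type / n_cells
    return X, F, list(cell_types)


class DeconvolutionEnsemble(BaseEstimator, RegressorMixin):
    """Ensemble of three softmax-output MLP regressors on the fraction simplex.

    scikit-learn estimator interface: ``fit(X, y)`` with X (n, G) normalized
    expression and y (n, T) fractions; ``predict`` returns simplex rows.
    Members are trained independently on identical data with AdamW and cosine
    annealing; the combine rule is the member mean renormalized to the
    simplex.  Fitted attributes carry a trailing underscore.

    Parameters
    ----------
    hidden_configs, dropouts : the three member architectures.
    loss : "mse" (default) on fractions, or "kl" for cross-entropy against
        the target composition.
    gene_ids : optional feature names enabling id-based reconciliation of
        external bulk matrices at predict time.
    """

    def __init__(
        self,
        hidden_configs=((256,), (512, 128), (512, 256, 64)),
        dropouts=(0.0, 0.2, 0.4),
        epochs: int = 40,
        batch_size: int = 128,
        lr: float = 1e-3,
        loss: str = "mse",
        seed: int = 0,
        gene_ids: list[str] | None = None,
    ):
        self.hidden_configs = hidden_configs
        self.dropouts = dropouts
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.loss = loss
        self.seed = seed
        self.gene_ids = gene_ids

    # -- internals -------------------------------------------------------------
    def _member_loss(self, logits: Tensor, y: np.ndarray) -> Tensor:
        probs = logits.softmax(axis=-1)
        if self.loss == "mse":
            diff = probs - Tensor(y.astype(np.float32))
            return (diff * diff).mean()
        if self.loss == "kl":
            return -(Tensor(y.astype(np.float32)) * (probs + 1e-12).log()).sum(axis=1).mean()
        raise ValueError(f"unknown loss {self.loss!r}")

    def _eval_member(self, member: MLP, X: np.ndarray, y: np.ndarray) -> float:
        return float(self._member_loss(member(Tensor(X)), y).data)

    def fit(self, X, y, X_val=None, y_val=None):
        X, gene_ids = self._coerce_X(X, fit=True)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("y must be (n_samples, n_types) aligned with X")
        if np.any(np.abs(y.sum(axis=1) - 1.0) > 1e-4):
            raise ValueError("every target row must lie on the simplex")
        self.gene_ids_ = gene_ids
        self.n_types_ = y.shape[1]
        self.scaler_mean_ = X.mean(axis=0)
        self.scaler_std_ = X.std(axis=0) + 1e-8
        Xs = ((X - self.scaler_mean_) / self.scaler_std_).astype(np.float32)
        if X_val is not None:
            Xv, _ = self._coerce_X(X_val, fit=False)
            Xv = ((Xv - self.scaler_mean_) / self.scaler_std_).astype(np.float32)
            yv = np.asarray(y_val, dtype=np.float64)
        else:
            Xv = yv = None

        self.members_ = []
        self.history_ = []
        n = Xs.shape[0]
        for m, (hidden, p_drop) in enumerate(zip(self.hidden_configs, self.dropouts)):
            rng = np.random.default_rng([self.seed, m])
            member = MLP(Xs.shape[1], tuple(hidden), self.n_types_, dropout=p_drop, rng=rng)
            opt = AdamW([{"params": member.parameters(), "lr": self.lr}])
            sched = CosineAnnealing(opt, t_max=self.epochs, eta_min=self.lr * 0.01)
            hist = {"train_loss": [], "val_loss": []}
            for _ in range(self.epochs):
                order = rng.permutation(n)
                epoch_loss = 0.0
                for start in range(0, n, self.batch_size):
                    idx = order[start : start + self.batch_size]
                    logits = member(Tensor(Xs[idx]), rng=rng, training=True)
                    loss = self._member_loss(logits, y[idx])
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    epoch_loss += float(loss.data) * idx.size
                sched.step()
                hist["train_loss"].append(epoch_loss / n)
                if Xv is not None:
                    hist["val_loss"].append(self._eval_member(member, Xv, yv))
            self.members_.append(member)
            self.history_.append(hist)
        return self

    def _coerce_X(self, X, fit: bool):
        """Return (array, gene_ids); reconcile DataFrame columns by gene id."""
        if isinstance(X, pd.DataFrame):
            if fit or not getattr(self, "gene_ids_", None):
                return X.to_numpy(dtype=np.float64), list(X.columns)
            want = self.gene_ids_
            have = set(X.columns)
            overlap = sum(g in have for g in want)
            if overlap < 0.5 * len(want):
                raise ValueError(
                    f"only {overlap}/{len(want)} model genes present in input; "
                    "refusing to extrapolate from <50% gene overlap"
                )
            missing = len(want) - overlap
            if missing:
                warnings.warn(f"{missing} model genes missing from input; imputed as 0")
            out = np.zeros((X.shape[0], len(want)), dtype=np.float64)
            for j, g in enumerate(want):
                if g in have:
                    out[:, j] = X[g].to_numpy(dtype=np.float64)
            return out, want
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        ids = self.gene_ids if fit else getattr(self, "gene_ids_", None)
        if not fit and X.shape[1] != len(self.scaler_mean_):
            raise ValueError("input gene dimension does not match the fitted model")
        return X, list(ids) if ids is not None else None

    def _member_probs(self, X: np.ndarray) -> np.ndarray:
        Xs = ((X - self.scaler_mean_) / self.scaler_std_).astype(np.float32)
        return np.stack([m(Tensor(Xs)).softmax(axis=-1).data for m in self.members_])

    def predict(self, X) -> np.ndarray:
        """Mean of member simplex outputs, renormalized; rows sum to 1."""
        X, _ = self._coerce_X(X, fit=False)
        mean = self._member_probs(X).mean(axis=0)
        return mean / mean.sum(axis=1, keepdims=True)

    def save(self, path) -> None:
        """Single-file checkpoint: config JSON + scaler + member weights."""
        import json

        arrays = {"scaler_mean": self.scaler_mean_, "scaler_std": self.scaler_std_}
        for m, member in enumerate(self.members_):
            for j, w in enumerate(member.state_dict()):
                arrays[f"member{m}_p{j}"] = w
        params = self.get_params()
        params["gene_ids"] = self.gene_ids_
        meta = {"params": params, "n_types": self.n_types_, "n_members": len(self.members_)}
        np.savez_compressed(path, meta=json.dumps(meta, default=list), **arrays)

    @classmethod
    def load(cls, path) -> "DeconvolutionEnsemble":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            params = meta["params"]
            for key in ("hidden_configs", "dropouts"):
                params[key] = tuple(tuple(h) if isinstance(h, list) else h for h in params[key])
            est = cls(**params)
            est.gene_ids_ = params["gene_ids"]
            est.n_types_ = meta["n_types"]
            est.scaler_mean_ = data["scaler_mean"]
            est.scaler_std_ = data["scaler_std"]
            est.members_ = []
            est.history_ = []
            g = len(est.scaler_mean_)
            for m, (hidden, p_drop) in enumerate(zip(est.hidden_configs, est.dropouts)):
                member = MLP(g, tuple(hidden), est.n_types_, dropout=p_drop, rng=np.random.default_rng(0))
                member.load_state_dict([data[f"member{m}_p{j}"] for j in range(len(member.parameters()))])
                est.members_.append(member)
        return est

    def validation_losses_(self, X, y) -> list[float]:
        """Per-member loss on (X, y), plus the ensemble-mean loss last."""
        X, _ = self._coerce_X(X, fit=False)
        y = np.asarray(y, dtype=np.float64)
        probs = self._member_probs(X)
        member_losses = [float(((p - y) ** 2).mean()) for p in probs]
        ens = probs.mean(axis=0)
        ens /= ens.sum(axis=1, keepdims=True)
        return member_losses + [float(((ens - y) ** 2).mean())]


# -- thin functional wrappers over the estimator -------------------------------

def train_ensemble(
    train: list[PseudoBulkSample],
    val: list[PseudoBulkSample],
    config: dict | None = None,
) -> DeconvolutionEnsemble:
    """Fit the three-member ensemble on pseudo-bulk sample lists."""
    config = dict(config or {})
    Xtr = np.stack([s.expression for s in train])
    ytr = np.stack([s.true_fractions for s in train])
    Xv = np.stack([s.expression for s in val])
    yv = np.stack([s.true_fractions for s in val])
    if Xtr.shape[1] != Xv.shape[1] or ytr.shape[1] != yv.shape[1]:
        raise ValueError("train/val gene or type dimensions disagree")
    est = DeconvolutionEnsemble(**config)
    return est.fit(Xtr, ytr, X_val=Xv, y_val=yv)


def predict_fractions(ens: DeconvolutionEnsemble, bulk) -> np.ndarray:
    """Per-sample simplex fractions for a bulk vector, matrix or DataFrame."""
    return ens.predict(bulk)


def pcc_eval(pred, truth) -> dict:
    """Pearson correlation of predicted vs true fractions.

    Returns per-sample PCC (across types; requires T >= 3) and per-type PCC
    (across samples).  Zero-variance vectors yield NaN and are flagged.
    """
    p = np.atleast_2d(np.asarray(pred, dtype=float))
    t = np.atleast_2d(np.asarray(truth, dtype=float))
    if p.shape != t.shape:
        raise ValueError("pred and truth must have identical shapes")

    def _pcc(a, b):
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    per_sample = (
        np.array([_pcc(p[i], t[i]) for i in range(p.shape[0])])
        if p.shape[1] >= 3
        else np.full(p.shape[0], np.nan)
    )
    per_type = np.array([_pcc(p[:, j], t[:, j]) for j in range(p.shape[1])])
    return {
        "per_sample": per_sample,
        "per_type": per_type,
        "n_undefined": int(np.isnan(per_sample).sum() + np.isnan(per_type).sum()),
    }
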