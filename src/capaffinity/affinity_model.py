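"""Feature assembly, label conversion, GBDT regression and evaluation.

The predictor is a single gradient-boosted decision-tree ensemble on the
3760-dim concatenation of the 1200-dim CAP nucleic vector with a 2560-dim
protein embedding.  Per-feature z-score standardization is fitted on
training rows only and applied to evaluation rows inside each fold.
pKd labels are converted to binding free energies via the factor
1.3633 kcal/mol per pKd unit (RT ln 10 at 298 K); the stored label is
-1.3633 * pKd so that stronger binders carry more negative dG.  Pearson
correlation and RMSE are sign-flip invariant, so this convention does not
affect any reported metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cap_features import NucleicSequence, cap_nucleic_vector
from .errors import UndefinedMetricError, ValidationError
from .facet_persistence import FiltrationGrid
from .protein_embed import EMBED_DIM, EmbeddingProvider, mock_provider

__all__ = [
    "PKD_TO_KCAL",
    "NUCLEIC_DIM",
    "COMBINED_DIM",
    "ModelConfig",
    "EvalReport",
    "assemble_features",
    "convert_label",
    "pcc",
    "rmse",
    "train",
    "cross_validate",
    "featurize_records",
]

#: kcal/mol per pKd unit (RT ln 10 at 298 K)
PKD_TO_KCAL = 1.3633

NUCLEIC_DIM = 1200
COMBINED_DIM = NUCLEIC_DIM + EMBED_DIM  # 3760


@dataclass(frozen=True)
class ModelConfig:
    """GBDT hyperparameters; defaults are the locked 'paper' profile."""

    n_estimators: int = 10_000
    max_depth: int = 7
    min_samples_split: int = 3
    learning_rate: float = 0.01
    max_features: str = "sqrt"
    subsample: float = 0.7
    random_state: int = 0
    standardize: bool = True
    loss: str = "squared_error"

    def __post_init__(self) -> None:
        if self.n_estimators <= 0 or self.max_depth <= 0:
            raise ValidationError("n_estimators and max_depth must be positive")
        if not 0 < self.subsample <= 1:
            raise ValidationError("subsample must lie in (0, 1]")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")

    @classmethod
    def paper(cls, random_state: int = 0) -> "ModelConfig":
        """Full-scale profile (10 000 estimators)."""
        return cls(random_state=random_state)

    @classmethod
    def fast(cls, random_state: int = 0) -> "ModelConfig":
        """Reduced profile for tests and quick runs: 500 estimators,
        all other hyperparameters unchanged."""
        return cls(n_estimators=500, random_state=random_state)


def assemble_features(
    nucleic: np.ndarray, protein: np.ndarray
) -> np.ndarray:
    """Concatenate a 1200-dim CAP vector with a 2560-dim protein embedding."""
    nucleic = np.asarray(nucleic, dtype=float)
    protein = np.asarray(protein, dtype=float)
    if nucleic.shape != (NUCLEIC_DIM,):
        raise ValidationError(
            f"nucleic vector must have length {NUCLEIC_DIM}, got {nucleic.shape}"
        )
    if protein.shape != (EMBED_DIM,):
        raise ValidationError(
            f"protein embedding must have length {EMBED_DIM}, got {protein.shape}"
        )
    return np.concatenate([nucleic, protein])


def featurize_records(
    records,
    provider: EmbeddingProvider | None = None,
    mode: str = "combined",
    grid: FiltrationGrid | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Build (ids, feature matrix, dG labels) from curated affinity records.

    ``mode`` selects the ablation arm: "combined" (3760), "nucleic" (1200)
    or "protein" (2560).  Labels are signed binding free energies.
    """
    if mode not in ("combined", "nucleic", "protein"):
        raise ValidationError(f"unknown feature mode {mode!r}")
    provider = provider or mock_provider()
    ids, rows, labels = [], [], []
    for rec in records:
        parts = []
        if mode in ("combined", "nucleic"):
            parts.append(
                cap_nucleic_vector(NucleicSequence(rec.na_seq, rec.na_type), grid)
            )
        if mode in ("combined", "protein"):
            parts.append(provider.embed(rec.protein_seq))
        ids.append(rec.id)
        rows.append(np.concatenate(parts))
        labels.append(convert_label(float(rec.pkd)))
    return ids, np.asarray(rows), np.asarray(labels)


def convert_label(pkd: float, signed: bool = True) -> float:
    """pKd -> binding free energy in kcal/mol.

    ``signed=True`` (default) returns -1.3633 * pKd, the physical dG sign.
    ``signed=False`` returns the scale-only magnitude 1.3633 * pKd, used
    when converting error magnitudes such as RMSEs between scales.
    """
    if not np.isfinite(pkd):
        raise ValidationError(f"pKd must be finite, got {pkd}")
    dg = PKD_TO_KCAL * float(pkd)
    return -dg if signed else dg


def pcc(y_exp: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation between experimental and predicted affinities."""
    a = np.asarray(y_exp, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("pcc needs two equal-length vectors of size >= 2")
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        raise UndefinedMetricError("pcc undefined for a zero-variance vector")
    return float((da * db).sum() / denom)


def rmse(y_exp: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-squared error over the samples."""
    a = np.asarray(y_exp, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError("rmse needs two equal-length vectors of size >= 1")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _make_pipeline(config: ModelConfig) -> Pipeline:
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "gbdt",
            GradientBoostingRegressor(
                n_estimators=config.n_estimators,
                max_depth=config.max_depth,
                min_samples_split=config.min_samples_split,
                learning_rate=config.learning_rate,
                max_features=config.max_features,
                subsample=config.subsample,
                random_state=config.random_state,
                loss=config.loss,
            ),
        )
    )
    return Pipeline(steps)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValidationError(
            f"need X (n, p) and y (n,); got {X.shape} and {y.shape}"
        )
    if not np.isfinite(X).all():
        raise ValidationError("feature matrix contains NaN or infinite values")
    if not np.isfinite(y).all():
        raise ValidationError("labels contain NaN or infinite values")
    return X, y


def train(X: np.ndarray, y: np.ndarray, config: ModelConfig | None = None) -> Pipeline:
    """Fit the scaler + GBDT pipeline; deterministic given (data, random_state)."""
    config = config or ModelConfig()
    X, y = _validate_xy(X, y)
    if X.shape[0] < 10:
        raise ValidationError(f"need at least 10 training rows, got {X.shape[0]}")
    pipe = _make_pipeline(config)
    pipe.fit(X, y)
    return pipe


@dataclass
class EvalReport:
    """Cross-validation report.

    ``per_seed`` holds one pooled out-of-fold PCC/RMSE per seed; the
    seed-level mean +/- sd is the multi-run protocol.  ``per_fold`` holds
    fold-level metrics for every (seed, fold); their mean +/- sd is the
    fold-level protocol.  Out-of-fold predictions partition the dataset
    exactly once per seed.
    """

    protocol: str
    k: int
    seeds: tuple[int, ...]
    per_seed: list[dict] = field(default_factory=list)
    per_fold: list[dict] = field(default_factory=list)
    predictions: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def mean_pcc(self) -> float:
        return float(np.mean([d["pcc"] for d in self.per_seed]))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([d["rmse"] for d in self.per_seed]))

    def summary(self) -> dict:
        seed_pcc = np.array([d["pcc"] for d in self.per_seed])
        seed_rmse = np.array([d["rmse"] for d in self.per_seed])
        fold_pcc = np.array([d["pcc"] for d in self.per_fold if d["pcc"] is not None])
        fold_rmse = np.array([d["rmse"] for d in self.per_fold])
        return {
            "protocol": self.protocol,
            "k": self.k,
            "n_seeds": len(self.seeds),
            "pcc_mean_over_seeds": float(seed_pcc.mean()),
            "pcc_sd_over_seeds": float(seed_pcc.std(ddof=0)),
            "rmse_mean_over_seeds": float(seed_rmse.mean()),
            "rmse_sd_over_seeds": float(seed_rmse.std(ddof=0)),
            "pcc_mean_over_folds": float(fold_pcc.mean()) if fold_pcc.size else None,
            "pcc_sd_over_folds": float(fold_pcc.std(ddof=0)) if fold_pcc.size else None,
            "rmse_mean_over_folds": float(fold_rmse.mean()),
            "rmse_sd_over_folds": float(fold_rmse.std(ddof=0)),
        }

    def to_json_dict(self) -> dict:
        out = self.summary()
        out["per_seed"] = self.per_seed
        out["per_fold"] = self.per_fold
        return out


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seeds: tuple[int, ...] = (0,),
    config: ModelConfig | None = None,
) -> EvalReport:
    """Shuffled k-fold cross-validation, repeated over seeds.

    Per seed: the data are split into k shuffled folds; for each fold a
    fresh pipeline (scaler fitted on the training rows only) is trained
    and the held-out rows predicted; pooled out-of-fold predictions give
    one PCC and RMSE per seed.  Fold-level metrics are also recorded
    (fold PCC is None for singleton or zero-variance folds).
    """
    config = config or ModelConfig()
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of rows n={n}")
    if k < 2:
        raise ValidationError("k must be at least 2")
    report = EvalReport(protocol="shuffled-kfold", k=k, seeds=tuple(seeds))
    for seed in seeds:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        oof = np.full(n, np.nan)
        for fold_idx, (tr, te) in enumerate(splitter.split(X)):
            pipe = _make_pipeline(config)
            pipe.fit(X[tr], y[tr])
            pred = pipe.predict(X[te])
            oof[te] = pred
            fold_pcc: float | None
            try:
                fold_pcc = pcc(y[te], pred)
            except (UndefinedMetricError, ValidationError):
                fold_pcc = None
            report.per_fold.append(
                {
                    "seed": int(seed),
                    "fold": fold_idx,
                    "n_test": int(te.size),
                    "pcc": fold_pcc,
                    "rmse": rmse(y[te], pred),
                }
            )
        if np.isnan(oof).any():
            raise AssertionError("out-of-fold predictions do not cover the data")
        report.per_seed.append(
            {"seed": int(seed), "pcc": pcc(y, oof), "rmse": rmse(y, oof)}
        )
        report.predictions[int(seed)] = oof
    return report
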