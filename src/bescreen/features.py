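"""Model inputs and targets: one-hot guide features, melting temperature,
per-position standardization, train/test splitting and dataset combination.

Feature layout is position-major one-hot over the 20-nt spacer (4 channels
per slot, ordered A, C, G, T; 80 columns) followed by one melting-
temperature column: 81 features in total.

Melting temperature is the nearest-neighbour thermodynamic Tm of the
spacer against its perfect complement, computed with Biopython's
``MeltingTemp.Tm_NN`` at its defaults: the Allawi & SantaLucia (1997)
DNA/DNA parameter table (``DNA_NN3``), 25 nM strand concentrations, 50 mM
Na+, and salt correction method 5.  Any fixed, documented parameter set
works here — the model needs a deterministic GC/stacking-correlated
covariate, not an absolute temperature.

Raw per-position editing rates are standardized per dataset: z = (r -
mu_p) / sigma_p with the population (ddof=0) mean/SD of that dataset at
that position.  Multi-dataset training sets are concatenations of
independently standardized datasets; z-scores are never re-standardized
after combining.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp
from sklearn.base import BaseEstimator, TransformerMixin

from .outcomes import BASES

logger = logging.getLogger(__name__)

SPACER_LENGTH = 20
N_FEATURES = 4 * SPACER_LENGTH + 1

#: per-position model range plus the any-position editing target
MODEL_POSITIONS: tuple = (3, 4, 5, 6, 7, 8, 9, 10, "overall")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def one_hot(spacer: str) -> np.ndarray:
    """Position-major one-hot encoding of a 20-nt spacer (80 binary values).

    Channel order is A, C, G, T within each of the 20 position slots.
    Ambiguity codes are rejected: guides containing N are excluded at
    ingestion rather than imputed.
    """
    if len(spacer) != SPACER_LENGTH:
        raise ValueError(f"spacer must be {SPACER_LENGTH} nt, got {len(spacer)}")
    vec = np.zeros(4 * SPACER_LENGTH)
    for i, b in enumerate(spacer):
        if b not in _BASE_INDEX:
            raise ValueError(f"invalid base {b!r} at spacer position {i + 1}")
        vec[4 * i + _BASE_INDEX[b]] = 1.0
    return vec


def decode_one_hot(vec: np.ndarray) -> str:
    """Inverse of :func:`one_hot`."""
    vec = np.asarray(vec)
    if vec.shape[0] < 4 * SPACER_LENGTH:
        raise ValueError("vector too short")
    out = []
    for i in range(SPACER_LENGTH):
        slot = vec[4 * i : 4 * i + 4]
        if slot.sum() != 1:
            raise ValueError(f"slot {i} is not one-hot")
        out.append(BASES[int(np.argmax(slot))])
    return "".join(out)


def melting_temperature(spacer: str) -> float:
    """Nearest-neighbour Tm (deg C) of the spacer vs its perfect complement."""
    if set(spacer) - set(BASES):
        raise ValueError(f"invalid alphabet in {spacer!r}")
    return float(MeltingTemp.Tm_NN(spacer))


def feature_names() -> list[str]:
    names = [f"pos{i + 1}_{b}" for i in range(SPACER_LENGTH) for b in BASES]
    names.append("melting_temperature")
    return names


class GuideFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: spacer strings -> 81-column feature matrix.

    80 one-hot sequence columns plus the spacer melting temperature.
    Compatible with sklearn pipelines; ``fit`` only validates input.
    """

    def fit(self, X, y=None):
        for s in X:
            one_hot(s)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        rows = [np.append(one_hot(s), melting_temperature(s)) for s in X]
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names())


class PositionStandardizer(BaseEstimator, TransformerMixin):
    """Per-position z-scoring of raw editing rates for one dataset.

    Fit on a rate table (rows = guides, columns = positions; NaN marks
    guides without an editable base at a position) and stores the
    population mean/SD per column.  ``transform`` maps rates to z-scores,
    ``inverse_transform`` back to rates; the round trip is exact.
    Positions with zero SD are degenerate and rejected.
    """

    def __init__(self, dataset_id: str = "dataset"):
        self.dataset_id = dataset_id

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        self.mean_ = {}
        self.std_ = {}
        for col in self.columns_:
            vals = X[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                raise ValueError(f"position {col}: no observations")
            sd = float(np.std(vals))  # population convention, ddof=0
            if sd <= 1e-12:
                raise ValueError(f"position {col}: zero variance, cannot standardize")
            self.mean_[col] = float(np.mean(vals))
            self.std_[col] = sd
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        out = X.copy().astype(float)
        for col in self.columns_:
            out[col] = (X[col] - self.mean_[col]) / self.std_[col]
        return out

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        Z = pd.DataFrame(Z)
        out = Z.copy().astype(float)
        for col in self.columns_:
            out[col] = Z[col] * self.std_[col] + self.mean_[col]
        return out


def standardize(
    rates: np.ndarray, mean: float, std: float
) -> np.ndarray:
    """z = (r - mean) / std, the per-position standardization."""
    if std <= 0:
        raise ValueError("standard deviation must be positive")
    return (np.asarray(rates, dtype=float) - mean) / std


def destandardize_z(z: np.ndarray, mean: float, std: float) -> np.ndarray:
    """Exact inverse of :func:`standardize` (no clipping)."""
    if std <= 0:
        raise ValueError("standard deviation must be positive")
    return np.asarray(z, dtype=float) * std + mean


def split_train_test(
    guide_ids: list[str], train_frac: float = 0.9, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Random disjoint, exhaustive train/test partition of guides.

    The test set size is floor(n * (1 - train_frac)), at least 1;
    reproducible under the seed.  Splitting is done per dataset before
    any combination across datasets.
    """
    n = len(guide_ids)
    if n < 10:
        raise ValueError("need at least 10 guides to split")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    # small epsilon so 100 * (1 - 0.9) floors to 10, not 9
    n_test = max(1, int(np.floor(n * (1.0 - train_frac) + 1e-9)))
    test_idx = set(perm[:n_test].tolist())
    train = [g for i, g in enumerate(guide_ids) if i not in test_idx]
    test = [g for i, g in enumerate(guide_ids) if i in test_idx]
    return train, test


def build_position_dataset(
    features: np.ndarray,
    guide_ids: list[str],
    rate_table: pd.DataFrame,
    dataset_id: str,
    split: dict[str, str],
) -> pd.DataFrame:
    """Assemble a PositionDataset table for one dataset.

    Columns: guide_id, dataset, split, the 81 feature columns, and one
    standardized-target column per position (z_<pos>, NaN where the guide
    has no editable base).  ``rate_table`` must already be standardized.
    """
    features = np.asarray(features)
    if features.shape[1] != N_FEATURES:
        raise ValueError(f"feature width must be {N_FEATURES}")
    df = pd.DataFrame(features, columns=feature_names())
    df.insert(0, "guide_id", guide_ids)
    df.insert(1, "dataset", dataset_id)
    df.insert(2, "split", [split[g] for g in guide_ids])
    for col in rate_table.columns:
        df[f"z_{col}"] = rate_table[col].to_numpy(dtype=float)
    return df


def rates_to_position_table(
    matrices: dict,
    library: dict,
    editor: str = "CBE",
    positions: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9, 10),
) -> pd.DataFrame:
    """Raw per-position model targets from corrected rate matrices.

    For each guide, the intended-transition rate at each position whose
    construct base is editable (NaN otherwise), plus an ``overall``
    column: the total fraction of reads carrying any substitution at any
    modeled position (sum of all substitution rates, clipped to 1 — an
    any-edit approximation that counts multi-edit reads once per edit).
    """
    from .simulate import intended_substitution

    ref, alt = intended_substitution(editor)
    rows = {}
    for gid, m in matrices.items():
        guide = library[gid]
        row = {}
        for p in positions:
            try:
                base = guide.base_at(p)
            except ValueError:
                base = None
            row[p] = m.rate(p, ref, alt) if base == ref else np.nan
        row["overall"] = float(min(1.0, m.rates.sum()))
        rows[gid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "guide_id"
    return table


def combine_datasets(datasets: list[pd.DataFrame]) -> pd.DataFrame:
    """Row-wise concatenation of per-dataset PositionDataset tables.

    Schemas must match exactly; per-dataset z-scores are kept as-is (no
    re-standardization after combining) and provenance is preserved in
    the ``dataset`` column.  Duplicate rows are allowed but warned about.
    """
    if not datasets:
        raise ValueError("no datasets to combine")
    cols = list(datasets[0].columns)
    for d in datasets[1:]:
        if list(d.columns) != cols:
            raise ValueError("dataset schemas do not match")
    combined = pd.concat(datasets, ignore_index=True)
    dup = combined.duplicated(subset=["guide_id", "dataset"]).sum()
    if dup:
        warnings.warn(f"{dup} duplicated (guide_id, dataset) rows after combining",
                      stacklevel=2)
    return combined
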