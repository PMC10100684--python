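"""Alpha diversity, rarefaction, Bray-Curtis beta diversity and
environment correlations.

Conventions: Shannon is reported in nats; Simpson is the Gini-Simpson index
1 - sum(p^2); Chao1 is the bias-corrected estimator (finite when no
doubletons); ACE uses the standard rare-taxon cutoff of 10.  Alpha indices
are computed on raw counts by default — rarefaction curves are a saturation
diagnostic, not a normalisation step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from skbio.diversity import alpha as skbio_alpha

from .otu import OtuTable, SampleMetadata

ALPHA_INDICES = ("richness", "shannon", "simpson", "pielou", "chao1", "ace")
TRANSFORMS = ("none", "log1p", "sqrt")


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    richness: int
    shannon: float
    simpson: float
    pielou: float
    chao1: float
    ace: float


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(frame.index), frame.to_numpy(float))


def _alpha_one(sample_id: str, counts: np.ndarray) -> AlphaDiversityRecord:
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError(f"sample {sample_id!r} has no counts")
    richness = int(counts.size)
    shannon = float(skbio_alpha.shannon(counts, base=np.e))
    simpson = float(skbio_alpha.simpson(counts))
    pielou = 0.0 if richness == 1 else shannon / np.log(richness)
    chao1 = float(skbio_alpha.chao1(counts, bias_corrected=True))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # skbio warns when all taxa are rare
            ace = float(skbio_alpha.ace(counts, rare_threshold=10))
    except ValueError:
        # ACE is undefined when every rare taxon is a singleton; fall back to
        # the bias-corrected Chao1 estimate for that sample
        ace = chao1
    # estimators never fall below the observed richness
    return AlphaDiversityRecord(
        sample_id, richness, shannon, simpson, pielou,
        max(chao1, float(richness)), max(ace, float(richness)),
    )


def compute_alpha(table: OtuTable) -> list[AlphaDiversityRecord]:
    """Per-sample alpha diversity (richness, Shannon, Gini-Simpson, Pielou,
    Chao1, ACE)."""
    counts = table.counts.to_numpy()
    return [
        _alpha_one(sample_id, counts[:, j]) for j, sample_id in enumerate(table.sample_ids)
    ]


def alpha_frame(records: list[AlphaDiversityRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(r) for r in records]).set_index("sample_id")
    return frame[list(ALPHA_INDICES)]


def rarefaction_curve(
    table: OtuTable,
    depths,
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean richness of without-replacement subsamples at each depth.

    Depths exceeding a sample's total are skipped for that sample (NaN) with
    a warning.  Returns a samples-by-depths frame of mean richness.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    depths = sorted(set(int(d) for d in depths))
    if any(d < 1 for d in depths):
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    totals = counts.sum(axis=0)
    out = np.full((table.n_samples, len(depths)), np.nan)
    for j, sample_id in enumerate(table.sample_ids):
        col = counts[:, j]
        for k, depth in enumerate(depths):
            if depth > totals[j]:
                warnings.warn(
                    f"depth {depth} exceeds total of sample {sample_id!r}; skipped"
                )
                continue
            if depth == totals[j]:
                out[j, k] = (col > 0).sum()
                continue
            richness = [
                np.count_nonzero(rng.multivariate_hypergeometric(col, depth))
                for _ in range(replicates)
            ]
            out[j, k] = float(np.mean(richness))
    return pd.DataFrame(out, index=table.sample_ids, columns=depths)


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return values.astype(float)
    if transform == "log1p":
        return np.log1p(values)
    if transform == "sqrt":
        return np.sqrt(values)
    raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def bray_curtis(table: OtuTable, transform: str = "none") -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples on optionally transformed
    abundances: d(x, y) = sum|x - y| / sum(x + y)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals().to_numpy()
    if (totals == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between all-zero samples")
    data = _transform(table.counts.to_numpy().T, transform)
    return DistanceMatrix(table.sample_ids, squareform(pdist(data, metric="braycurtis")))


def env_correlations(
    records: list[AlphaDiversityRecord],
    metadata: SampleMetadata,
    variables=("salinity", "temperature"),
) -> pd.DataFrame:
    """Spearman correlations of every alpha index against each environmental
    variable (the diversity-vs-salinity/temperature table).

    Ties get average ranks; two-sided p-values use the t approximation.
    A constant variable yields a flagged NaN row rather than an error.
    """
    alpha = alpha_frame(records)
    missing = set(alpha.index) - set(metadata.sample_ids)
    if missing:
        raise ValueError(f"metadata missing samples: {sorted(missing)}")
    if len(alpha) < 4:
        raise ValueError("need at least 4 samples for rank correlations")
    env = metadata.frame.loc[alpha.index]
    rows = []
    for variable in variables:
        x = env[variable].to_numpy(float)
        constant = np.ptp(x) == 0
        for index in ALPHA_INDICES:
            if constant or np.ptp(alpha[index].to_numpy(float)) == 0:
                rows.append((index, variable, np.nan, np.nan, "constant input"))
                continue
            r, p = spearmanr(alpha[index].to_numpy(float), x)
            rows.append((index, variable, float(r), float(p), ""))
    return pd.DataFrame(rows, columns=["index", "variable", "spearman_r", "p_value", "note"])
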