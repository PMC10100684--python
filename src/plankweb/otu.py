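"""OTU table and sample metadata containers.

The central data structure is :class:`OtuTable`: a taxa-by-samples matrix of
non-negative integer counts with optional taxonomy strings and a per-taxon
domain flag (prokaryote vs microeukaryote).  Tables round-trip through a plain
TSV format: first column is the taxon id, one column per sample, and an
optional trailing ``taxonomy`` column whose value carries a ``prok|`` or
``euk|`` prefix encoding the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PROKARYOTE = "prokaryote"
MICROEUKARYOTE = "microeukaryote"

_DOMAIN_PREFIX = {"prok": PROKARYOTE, "euk": MICROEUKARYOTE}
_DOMAIN_TO_PREFIX = {v: k for k, v in _DOMAIN_PREFIX.items()}


@dataclass
class SampleMetadata:
    """Per-sample environmental metadata (salinity gradient design).

    Attributes
    ----------
    frame : pandas.DataFrame
        Indexed by sample id with at least the columns ``salinity`` (psu),
        ``temperature`` (degrees C) and ``region`` (group label).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"salinity", "temperature", "region"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))


@dataclass
class OtuTable:
    """Taxa-by-samples count matrix with optional taxonomy and domain labels.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are taxa, columns are samples, entries non-negative integers.
    taxonomy : pandas.Series, optional
        Lineage string per taxon, aligned with ``counts.index``.
    domain : pandas.Series, optional
        ``"prokaryote"`` or ``"microeukaryote"`` per taxon.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    domain: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate taxon ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        for attr in ("taxonomy", "domain"):
            series = getattr(self, attr)
            if series is not None and not series.index.equals(self.counts.index):
                raise ValueError(f"{attr} index does not match taxon ids")
        if self.domain is not None:
            bad = set(self.domain.dropna()) - {PROKARYOTE, MICROEUKARYOTE}
            if bad:
                raise ValueError(f"unknown domain labels: {sorted(bad)}")

    # ------------------------------------------------------------------ views
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Within-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total counts: {empty}")
        return self.counts / totals

    def mean_relative_abundance(self) -> pd.Series:
        """Per-taxon mean of within-sample relative abundances."""
        return self.relative_abundance().mean(axis=1)

    def presence_absence(self) -> pd.DataFrame:
        return (self.counts > 0).astype(np.int8)

    # --------------------------------------------------------------- subsets
    def select_taxa(self, taxon_ids) -> "OtuTable":
        taxonomy = self.taxonomy.loc[taxon_ids] if self.taxonomy is not None else None
        domain = self.domain.loc[taxon_ids] if self.domain is not None else None
        return OtuTable(self.counts.loc[taxon_ids], taxonomy, domain)

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts[list(sample_ids)], self.taxonomy, self.domain)

    def select_domain(self, domain: str) -> "OtuTable":
        if self.domain is None:
            raise ValueError("table carries no domain labels")
        keep = self.domain.index[self.domain == domain]
        if len(keep) == 0:
            raise ValueError(f"no taxa with domain {domain!r}")
        return self.select_taxa(keep)

    # -------------------------------------------------------------------- IO
    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        if self.taxonomy is not None or self.domain is not None:
            lineage = (
                self.taxonomy
                if self.taxonomy is not None
                else pd.Series("", index=self.counts.index)
            )
            if self.domain is not None:
                prefix = self.domain.map(_DOMAIN_TO_PREFIX).fillna("")
                lineage = prefix.str.cat(lineage, sep="|").str.rstrip("|")
            out["taxonomy"] = lineage
        out.to_csv(path, sep="\t", index_label="taxon_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OtuTable":
        frame = pd.read_csv(path, sep="\t", index_col="taxon_id")
        taxonomy = domain = None
        if "taxonomy" in frame.columns:
            raw = frame.pop("taxonomy").astype(str)
            prefix = raw.str.split("|").str[0]
            domain = prefix.map(_DOMAIN_PREFIX)
            taxonomy = raw.str.split("|", n=1).str[1].fillna("")
            if domain.isna().all():
                domain, taxonomy = None, raw
        return cls(frame, taxonomy, domain)
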