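"""PER-SIMPER deviation analysis and the dispersal-niche continuum index.

The idea: decompose the observed between-group dissimilarity into ranked
per-taxon SIMPER contributions, then ask which constrained randomisation of
the presence-absence matrix can reproduce that ranked profile.

Three null schemes:

``fix_taxa_totals`` ("dispersal")
    each taxon keeps its occupancy count, site assignments randomised —
    preserves dispersal-type structure carried by species occurrences;
``fix_site_totals`` ("niche")
    each site keeps its richness, taxon identities randomised — preserves
    niche-type structure carried by site capacities;
``fix_both``
    both margins preserved via checkerboard-swap MCMC — the reference null.

For each null matrix the deviation from the observed ranked profile is
E = log10(sum of squared rank-wise differences in contribution %).  The
standardized effect sizes

    SES_x = (mean(E_x) - mean(E_both)) / sd(E_both)

for x in {dispersal, niche} yield DNCI = SES_dispersal - SES_niche:
negative values mean the dispersal-type null deviates less, i.e. dispersal
assembly dominates; positive values indicate niche assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .otu import OtuTable

#: Scheme-to-process mapping.  Kept in one place: the dispersal-type null
#: preserves taxon occupancy totals, the niche-type null preserves site
#: richness totals.
SCHEME_FOR_PROCESS = {"dispersal": "fix_taxa_totals", "niche": "fix_site_totals"}

E_FLOOR = -12.0  # floor for log10 of an exactly-zero deviation

SCHEMES = ("fix_taxa_totals", "fix_site_totals", "fix_both")


@dataclass
class DnciResult:
    group_pair: tuple[str, str]
    e_dispersal: np.ndarray
    e_niche: np.ndarray
    e_both: np.ndarray
    ses_dispersal: float
    ses_niche: float
    dnci: float
    n_permutations: int

    def to_json_dict(self) -> dict:
        return {
            "group_pair": list(self.group_pair),
            "SES_dispersal": self.ses_dispersal,
            "SES_niche": self.ses_niche,
            "DNCI": self.dnci,
            "n_permutations": self.n_permutations,
        }


def _contributions(pa: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Per-taxon SIMPER contribution (%) to mean between-group Bray-Curtis
    dissimilarity of a presence-absence matrix (taxa x sites)."""
    a, b = pa[:, mask_a], pa[:, mask_b]
    # pairwise per-taxon |x - y| over all between-group site pairs
    diff = np.abs(a[:, :, None] - b[:, None, :]).astype(float)
    denom = (a.sum(axis=0)[:, None] + b.sum(axis=0)[None, :]).astype(float)
    valid = denom > 0
    if not valid.any():
        raise ValueError("no turnover: all between-group site pairs are empty")
    contrib = np.where(valid[None, :, :], diff / np.where(valid, denom, 1.0)[None], 0.0)
    per_taxon = contrib.sum(axis=(1, 2)) / valid.sum()
    total = per_taxon.sum()
    if total <= 0:
        raise ValueError("no turnover: between-group dissimilarities are all zero")
    return 100.0 * per_taxon / total


def simper_profile(pa: np.ndarray, groups, taxon_ids=None) -> pd.DataFrame:
    """Ranked SIMPER decomposition of mean between-group dissimilarity.

    Parameters
    ----------
    pa : taxa-by-sites 0/1 matrix
    groups : per-site labels with exactly two distinct values, each with at
        least two sites

    Returns a frame sorted by descending contribution; contributions sum to
    100.  Taxa absent from every site are dropped with a warning.
    """
    pa = np.asarray(pa)
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("SIMPER needs exactly two groups")
    if min((labels == u).sum() for u in uniq) < 2:
        raise ValueError("each group needs at least 2 sites")
    if taxon_ids is None:
        taxon_ids = [f"t{i}" for i in range(pa.shape[0])]
    empty = pa.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} taxa absent from all sites")
        pa = pa[~empty]
        taxon_ids = [t for t, e in zip(taxon_ids, empty) if not e]
    pct = _contributions(pa, labels == uniq[0], labels == uniq[1])
    frame = pd.DataFrame({"taxon_id": taxon_ids, "contribution_pct": pct})
    return frame.sort_values("contribution_pct", ascending=False, ignore_index=True)


def e_metric(observed_pct: np.ndarray, permuted_pct: np.ndarray) -> float:
    """PER-SIMPER deviation between two rank-ordered contribution profiles:
    log10 of the summed squared rank-wise differences, floored at -12."""
    obs = np.sort(np.asarray(observed_pct, float))[::-1]
    perm = np.sort(np.asarray(permuted_pct, float))[::-1]
    if obs.shape != perm.shape:
        raise ValueError("profiles must have the same length")
    dev = float(np.sum((obs - perm) ** 2))
    if dev <= 10.0**E_FLOOR:
        return E_FLOOR
    return float(np.log10(dev))


# ------------------------------------------------------------------ null models
def _shuffle_rows(pa: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random matrix with every row (taxon) total preserved."""
    ranks = rng.random(pa.shape).argsort(axis=1).argsort(axis=1)
    return (ranks < pa.sum(axis=1)[:, None]).astype(pa.dtype)


def _swap_mcmc(
    current: np.ndarray, n_attempts: int, rng: np.random.Generator
) -> int:
    """Attempt ``n_attempts`` checkerboard swaps in place; returns the number
    of successful swaps.  Each swap preserves both margins."""
    n_rows, n_cols = current.shape
    rows = rng.integers(0, n_rows, size=(n_attempts, 2))
    cols = rng.integers(0, n_cols, size=(n_attempts, 2))
    done = 0
    for (i, j), (k, l) in zip(rows, cols):
        if i == j or k == l:
            continue
        a, b, c, d = current[i, k], current[i, l], current[j, k], current[j, l]
        if a == d and b == c and a != b:
            current[i, k], current[i, l] = b, a
            current[j, k], current[j, l] = d, c
            done += 1
    return done


def null_matrices(
    pa: np.ndarray, scheme: str, n: int, seed: int = 0
) -> list[np.ndarray]:
    """Draw ``n`` randomised presence-absence matrices under a scheme.

    All schemes preserve the total fill.  ``fix_both`` runs a checkerboard
    swap chain with burn-in 10x fill and thinning fill/2 attempted swaps
    between samples; if the matrix admits no checkerboard swap at all the
    chain cannot move and copies are returned with a warning.
    """
    pa = np.asarray(pa)
    if ((pa != 0) & (pa != 1)).any():
        raise ValueError("matrix must be 0/1")
    if (pa.sum(axis=1) == 0).any() or (pa.sum(axis=0) == 0).any():
        raise ValueError("matrix has empty rows or columns")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    if scheme == "fix_taxa_totals":
        return [_shuffle_rows(pa, rng) for _ in range(n)]
    if scheme == "fix_site_totals":
        return [_shuffle_rows(pa.T, rng).T for _ in range(n)]
    fill = int(pa.sum())
    current = pa.copy()
    burned = _swap_mcmc(current, 10 * fill, rng)
    if burned == 0:
        warnings.warn("no checkerboard swaps possible; fix_both returns copies")
        return [pa.copy() for _ in range(n)]
    thin = max(fill // 2, 1)
    out = []
    for _ in range(n):
        _swap_mcmc(current, thin, rng)
        out.append(current.copy())
    return out


def dnci_pair(
    pa: np.ndarray,
    groups,
    taxon_ids=None,
    n_permutations: int = 999,
    seed: int = 0,
) -> DnciResult:
    """DNCI for one pair of site groups on a presence-absence matrix."""
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("dnci_pair needs exactly two groups")
    sizes = [(labels == u).sum() for u in uniq]
    if min(sizes) < 4:
        warnings.warn("groups with fewer than 4 sites give unstable DNCI")
    pa = np.asarray(pa)
    keep = pa.sum(axis=1) > 0
    pa = pa[keep]
    if taxon_ids is not None:
        taxon_ids = [t for t, k in zip(taxon_ids, keep) if k]
    observed = simper_profile(pa, labels, taxon_ids)["contribution_pct"].to_numpy()

    e_samples: dict[str, np.ndarray] = {}
    for offset, scheme in enumerate(SCHEMES):
        nulls = null_matrices(pa, scheme, n_permutations, seed=seed + offset)
        values = np.empty(n_permutations)
        for idx, null in enumerate(nulls):
            null_pct = _null_contributions(null, labels, uniq)
            values[idx] = e_metric(observed, null_pct)
        e_samples[scheme] = values

    e_both = e_samples["fix_both"]
    sd_both = float(e_both.std(ddof=1))
    if sd_both == 0:
        raise ValueError("fix_both E values are constant; SES undefined")
    ses = {
        process: (e_samples[scheme].mean() - e_both.mean()) / sd_both
        for process, scheme in SCHEME_FOR_PROCESS.items()
    }
    return DnciResult(
        group_pair=(str(uniq[0]), str(uniq[1])),
        e_dispersal=e_samples["fix_taxa_totals"],
        e_niche=e_samples["fix_site_totals"],
        e_both=e_both,
        ses_dispersal=float(ses["dispersal"]),
        ses_niche=float(ses["niche"]),
        dnci=float(ses["dispersal"] - ses["niche"]),
        n_permutations=n_permutations,
    )


def _null_contributions(null: np.ndarray, labels: np.ndarray, uniq) -> np.ndarray:
    """Contribution profile of a null matrix, tolerating taxa that the
    randomisation emptied (they contribute zero)."""
    occupied = null.sum(axis=1) > 0
    pct = np.zeros(null.shape[0])
    pct[occupied] = _contributions(null[occupied], labels == uniq[0], labels == uniq[1])
    return pct


def dnci(
    table: OtuTable,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[DnciResult]:
    """DNCI for every pair of site groups in an OTU table.

    The table is reduced to presence-absence.  With more than two groups a
    result is returned per pair; average the ``dnci`` fields for an overall
    value.
    """
    labels = np.asarray(list(groups))
    if len(labels) != table.n_samples:
        raise ValueError("groups length does not match samples")
    pa = table.presence_absence().to_numpy()
    results = []
    for pair_idx, (g1, g2) in enumerate(combinations(sorted(set(labels)), 2)):
        mask = (labels == g1) | (labels == g2)
        results.append(
            dnci_pair(
                pa[:, mask],
                labels[mask],
                taxon_ids=table.taxon_ids,
                n_permutations=n_permutations,
                seed=seed + 1000 * pair_idx,
            )
        )
    return results
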