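"""Synthetic community generators with known ground truth.

Four regimes, each mirroring one downstream analysis:

``neutral``
    The generative twin of the Sloan neutral community model: each taxon's
    local relative abundance is Beta(N m p, N m (1 - p)) around its
    metacommunity frequency p, with N the library size and m the migration
    rate, then counts are binomial.  Fitting the neutral model to such a
    table should recover m.
``niche``
    Salinity-sorted communities: samples fall into gradient groups, taxa have
    Gaussian responses around salinity optima, counts are multinomial.
``dispersal``
    Occupancy-driven presence/absence: each taxon occupies sites
    independently at its own probability, with no site effect — the
    signature the dispersal-type null model preserves.
``block_network``
    Module-structured abundances: taxa within a module share a latent
    log-normal factor per sample, inducing strong positive rank correlation;
    the within-module pair set is the ground-truth edge set for network
    inference.

Metacommunity relative abundances are drawn by stick-breaking (GEM) with a
concentration parameter, giving the long-tailed rank-abundance shape typical
of amplicon surveys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .otu import MICROEUKARYOTE, PROKARYOTE, OtuTable, SampleMetadata

REGIMES = ("neutral", "niche", "dispersal", "block_network")

#: Default salinity design: (region label, mean psu, sd psu) for the
#: offshore shelf, the nearshore transition and the river estuary.
DEFAULT_GRADIENT_GROUPS = (
    ("estuary", 13.15, 0.93),
    ("nearshore", 17.28, 0.56),
    ("offshore", 29.17, 0.24),
)


@dataclass
class CommunitySimSpec:
    """Parameters of one synthetic community draw.

    Attributes
    ----------
    n_taxa, n_samples, reads_per_sample : int
        Table dimensions and library size.
    regime : str
        One of ``neutral``, ``niche``, ``dispersal``, ``block_network``.
    m : float
        Migration probability in (0, 1]; neutral regime only.
    n_modules : int
        Number of co-occurrence modules; block_network regime only.
    gradient_groups : sequence of (label, mean_psu, sd_psu)
        Salinity design; niche regime only.
    niche_width : float
        Gaussian response width (psu) of taxa around their salinity optimum;
        larger widths flatten the niche signal.
    optima_skew : float
        Beta(1, skew) placement of salinity optima over the gradient span:
        1 gives uniform optima; larger values crowd optima toward the
        freshwater end, so richness declines toward high salinity the way a
        river-fed species pool does.
    gem_concentration : float
        Stick-breaking concentration of the metacommunity abundances.
    factor_loading, noise_sd : float
        Latent-factor strength and residual log-scale noise of the
        block_network regime.
    seed : int
        Root seed; every stochastic draw derives from it.
    """

    n_taxa: int
    n_samples: int
    reads_per_sample: int
    regime: str
    m: float | None = None
    n_modules: int | None = None
    gradient_groups: tuple = DEFAULT_GRADIENT_GROUPS
    niche_width: float = 3.0
    optima_skew: float = 1.0
    gem_concentration: float = 5.0
    factor_loading: float = 2.0
    noise_sd: float = 0.3
    module_chain_rho: float = 0.65
    occupancy_probs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.regime == "neutral":
            if self.m is None or not (0.0 < self.m <= 1.0):
                raise ValueError("neutral regime requires migration rate m in (0, 1]")
        if self.regime == "niche":
            if not self.gradient_groups:
                raise ValueError("niche regime requires non-empty gradient_groups")
            if any(sd < 0 for _, _, sd in self.gradient_groups):
                raise ValueError("group salinity sds must be >= 0")
            if self.niche_width <= 0:
                raise ValueError("niche_width must be > 0")
            if self.optima_skew < 1.0:
                raise ValueError("optima_skew must be >= 1")
        if self.regime == "block_network":
            if self.n_modules is None or self.n_modules < 2:
                raise ValueError("block_network regime requires n_modules >= 2")
            if self.n_modules > self.n_taxa:
                raise ValueError("n_modules cannot exceed n_taxa")

    def rng(self, stage: str) -> np.random.Generator:
        """Substream generator for a named stage.

        A single root seed is split with ``SeedSequence.spawn_key`` keyed by
        a stable per-stage index, so each stage's stream is reproducible in
        isolation.
        """
        stage_key = int(np.frombuffer(stage.encode().ljust(8, b"\0")[:8], "<u8")[0] % (2**31))
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage_key,)))


@dataclass
class GroundTruth:
    """What the generator knows that the analyses must recover."""

    metacommunity_abundances: np.ndarray
    true_m: float | None = None
    niche_optima: np.ndarray | None = None
    module_assignment: np.ndarray | None = None
    true_edges: set[tuple[str, str]] | None = None
    occupancy_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.metacommunity_abundances, float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("metacommunity abundances must be >= 0 and sum to 1")
        self.metacommunity_abundances = p

    def to_json(self, path: str | Path, taxon_ids: list[str] | None = None) -> None:
        payload: dict = {
            "metacommunity_abundances": self.metacommunity_abundances.tolist(),
            "true_m": self.true_m,
        }
        for name in ("niche_optima", "module_assignment", "occupancy_probs"):
            value = getattr(self, name)
            payload[name] = None if value is None else np.asarray(value).tolist()
        payload["true_edges"] = (
            None if self.true_edges is None else sorted(map(list, self.true_edges))
        )
        if taxon_ids is not None:
            payload["taxon_ids"] = list(taxon_ids)
        Path(path).write_text(json.dumps(payload, indent=1))


def stick_breaking_abundances(
    n_taxa: int, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Metacommunity relative abundances from a GEM(concentration) draw.

    The leftover stick mass after ``n_taxa`` breaks is folded back by
    normalisation so the vector sums to exactly one.
    """
    betas = rng.beta(1.0, concentration, size=n_taxa)
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - betas[:-1])])
    weights = betas * remaining
    return weights / weights.sum()


def _taxon_ids(n_taxa: int, prefix: str = "OTU") -> list[str]:
    width = len(str(n_taxa))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n_taxa)]


def _sample_ids(n_samples: int) -> list[str]:
    width = len(str(n_samples))
    return [f"LF{i + 1:0{width}d}" for i in range(n_samples)]


def _as_table(counts: np.ndarray, taxon_ids, sample_ids, domain: str | None = None) -> OtuTable:
    frame = pd.DataFrame(counts, index=taxon_ids, columns=sample_ids)
    dom = pd.Series(domain, index=frame.index) if domain else None
    return OtuTable(frame, domain=dom)


# --------------------------------------------------------------------- neutral
def simulate_neutral(spec: CommunitySimSpec) -> tuple[OtuTable, GroundTruth]:
    """Neutral assembly at migration rate ``spec.m``.

    Per taxon i with metacommunity frequency p_i and per sample: the local
    relative abundance is Beta(N m p_i, N m (1 - p_i)) with
    N = ``reads_per_sample``, then counts are Binomial(N, abundance).
    """
    if spec.regime != "neutral":
        raise ValueError("spec.regime must be 'neutral'")
    rng = spec.rng("neutral")
    p = stick_breaking_abundances(spec.n_taxa, spec.gem_concentration, rng)
    # clamp away from 0/1 so both Beta shape parameters stay positive
    p_safe = np.clip(p, 1e-12, 1.0 - 1e-12)
    nm = spec.reads_per_sample * spec.m
    local = rng.beta(
        nm * p_safe[:, None],
        nm * (1.0 - p_safe[:, None]),
        size=(spec.n_taxa, spec.n_samples),
    )
    counts = rng.binomial(spec.reads_per_sample, local)
    table = _as_table(counts, _taxon_ids(spec.n_taxa), _sample_ids(spec.n_samples))
    return table, GroundTruth(metacommunity_abundances=p, true_m=spec.m)


# ----------------------------------------------------------------------- niche
def simulate_niche_gradient(
    spec: CommunitySimSpec,
) -> tuple[OtuTable, GroundTruth, SampleMetadata]:
    """Salinity-sorted communities along a grouped gradient.

    Samples are split as evenly as possible across the gradient groups and
    given Normal(mean, sd) salinities.  Each taxon has a salinity optimum
    (uniform over the observed gradient span, slightly widened) and a shared
    Gaussian response width; expected abundance is the metacommunity
    frequency times the response, and counts are one multinomial draw of the
    library size per sample.  Temperature decreases with salinity (estuary
    warmer than shelf) with mild noise, mirroring a river-to-sea transect.
    """
    if spec.regime != "niche":
        raise ValueError("spec.regime must be 'niche'")
    rng = spec.rng("niche")
    groups = list(spec.gradient_groups)
    n_groups = len(groups)
    base, extra = divmod(spec.n_samples, n_groups)
    sizes = [base + (1 if i < extra else 0) for i in range(n_groups)]
    if any(s == 0 for s in sizes):
        raise ValueError("n_samples too small for the number of gradient groups")

    labels, salinity = [], []
    for (label, mean, sd), size in zip(groups, sizes):
        labels.extend([label] * size)
        salinity.append(rng.normal(mean, sd, size=size))
    salinity = np.concatenate(salinity)
    temperature = 12.0 - 0.3 * (salinity - salinity.min()) + rng.normal(0.0, 0.4, spec.n_samples)

    p = stick_breaking_abundances(spec.n_taxa, spec.gem_concentration, rng)
    lo, hi = salinity.min() - 2.0, salinity.max() + 2.0
    optima = lo + (hi - lo) * rng.beta(1.0, spec.optima_skew, size=spec.n_taxa)
    response = np.exp(
        -((salinity[None, :] - optima[:, None]) ** 2) / (2.0 * spec.niche_width**2)
    )
    expected = p[:, None] * response
    expected /= expected.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(spec.reads_per_sample, expected[:, j]) for j in range(spec.n_samples)]
    )
    sample_ids = _sample_ids(spec.n_samples)
    table = _as_table(counts, _taxon_ids(spec.n_taxa), sample_ids)
    metadata = SampleMetadata(
        pd.DataFrame(
            {"salinity": salinity, "temperature": temperature, "region": labels},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = GroundTruth(metacommunity_abundances=p, niche_optima=optima)
    return table, truth, metadata


# ------------------------------------------------------------------- dispersal
def simulate_dispersal_structured(spec: CommunitySimSpec) -> tuple[OtuTable, GroundTruth]:
    """Occupancy-driven tables with no site effect.

    Each taxon receives an occupancy probability; presence at each site is an
    independent Bernoulli draw at that probability, and abundance conditional
    on presence is i.i.d. log-normal across sites (rounded up to at least one
    read).  All structure lives in the taxon margin — the situation a
    taxon-totals-preserving null model reproduces.
    """
    if spec.regime != "dispersal":
        raise ValueError("spec.regime must be 'dispersal'")
    rng = spec.rng("dispersal")
    if spec.occupancy_probs is not None:
        occupancy = np.asarray(spec.occupancy_probs, float)
        if occupancy.shape != (spec.n_taxa,):
            raise ValueError("occupancy_probs must have length n_taxa")
    else:
        occupancy = rng.beta(1.5, 1.5, size=spec.n_taxa)
    present = rng.random((spec.n_taxa, spec.n_samples)) < occupancy[:, None]
    p = stick_breaking_abundances(spec.n_taxa, spec.gem_concentration, rng)
    scale = spec.reads_per_sample * p[:, None]
    abundance = np.ceil(scale * rng.lognormal(0.0, 0.5, size=present.shape))
    counts = np.where(present, np.maximum(abundance, 1.0), 0.0).astype(np.int64)
    table = _as_table(counts, _taxon_ids(spec.n_taxa), _sample_ids(spec.n_samples))
    truth = GroundTruth(metacommunity_abundances=p, occupancy_probs=occupancy)
    return table, truth


# --------------------------------------------------------------- block network
def simulate_block_network(spec: CommunitySimSpec) -> tuple[OtuTable, GroundTruth]:
    """Module-structured abundances with known co-occurrence edges and
    gatekeeper taxa bridging adjacent modules.

    Per sample each module draws a latent standard-normal factor; factors of
    adjacent modules form an AR(1)-style chain with neighbour correlation
    ``module_chain_rho``, keeping between-module taxon correlations well
    below the network threshold while letting bridge taxa exist at all (a
    taxon cannot correlate above 1/sqrt(2) with two *independent* factors).
    A member taxon's log-abundance is its baseline plus ``factor_loading``
    times its module factor plus ``noise_sd`` residual noise; counts are
    Poisson around the exponentiated latent scaled to the library size.

    The last ``n_modules - 1`` taxa are gatekeepers: taxon k loads equally
    on modules k and k+1 (unit-variance mixture), so it correlates ~0.85
    with both blocks — above the 0.8 edge threshold — and holds the network
    together exactly the way high-betweenness gatekeeper taxa do in real
    co-occurrence networks.  Ground-truth edges are all within-module pairs
    plus each gatekeeper's pairs with both modules it spans; gatekeepers
    carry module id -1 in ``module_assignment``.
    """
    if spec.regime != "block_network":
        raise ValueError("spec.regime must be 'block_network'")
    rng = spec.rng("block")
    n_bridges = spec.n_modules - 1
    n_members = spec.n_taxa - n_bridges
    if n_members < spec.n_modules:
        raise ValueError("n_taxa too small for modules plus gatekeepers")
    modules = np.sort(np.arange(n_members) % spec.n_modules)
    # gatekeepers get upper-middle-rank abundances: never the dominant taxa,
    # but sampled deeply enough that Poisson noise cannot sever their edges
    p_sorted = np.sort(stick_breaking_abundances(spec.n_taxa, spec.gem_concentration, rng))[::-1]
    bridge_ranks = spec.n_taxa // 4 + np.arange(n_bridges)
    member_ranks = np.setdiff1d(np.arange(spec.n_taxa), bridge_ranks)
    p = np.empty(spec.n_taxa)
    p[:n_members] = p_sorted[member_ranks]
    p[n_members:] = p_sorted[bridge_ranks]

    rho = spec.module_chain_rho
    eps = rng.normal(0.0, 1.0, size=(spec.n_modules, spec.n_samples))
    # whiten the innovations so the realised factor geometry is exact:
    # sampling drift in factor correlations would otherwise blur the
    # ground-truth edge set the acceptance checks score against
    eps = eps - eps.mean(axis=1, keepdims=True)
    cov = eps @ eps.T / (spec.n_samples - 1)
    eps = np.linalg.inv(np.linalg.cholesky(cov)) @ eps
    factors = np.empty_like(eps)
    factors[0] = eps[0]
    for k in range(1, spec.n_modules):
        factors[k] = rho * factors[k - 1] + np.sqrt(1.0 - rho**2) * eps[k]

    latent_factor = np.empty((spec.n_taxa, spec.n_samples))
    latent_factor[:n_members] = factors[modules, :]
    for b in range(n_bridges):
        latent_factor[n_members + b] = (factors[b] + factors[b + 1]) / np.sqrt(
            2.0 * (1.0 + rho)
        )
    log_latent = (
        np.log(p[:, None] * spec.reads_per_sample)
        + spec.factor_loading * latent_factor
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_taxa, spec.n_samples))
    )
    counts = rng.poisson(np.exp(log_latent))
    taxon_ids = _taxon_ids(spec.n_taxa)
    assignment = np.concatenate([modules, np.full(n_bridges, -1)])
    edges = {
        (taxon_ids[i], taxon_ids[j])
        for i in range(n_members)
        for j in range(i + 1, n_members)
        if modules[i] == modules[j]
    }
    for b in range(n_bridges):
        bridge = taxon_ids[n_members + b]
        for i in range(n_members):
            if modules[i] in (b, b + 1):
                edges.add(tuple(sorted((bridge, taxon_ids[i]))))
        if b + 1 < n_bridges:  # adjacent gatekeepers share a module factor
            edges.add(tuple(sorted((bridge, taxon_ids[n_members + b + 1]))))
    table = _as_table(counts, taxon_ids, _sample_ids(spec.n_samples))
    truth = GroundTruth(
        metacommunity_abundances=p, module_assignment=assignment, true_edges=edges
    )
    return table, truth


def simulate(spec: CommunitySimSpec):
    """Dispatch on ``spec.regime``; niche additionally returns metadata."""
    return {
        "neutral": simulate_neutral,
        "niche": simulate_niche_gradient,
        "dispersal": simulate_dispersal_structured,
        "block_network": simulate_block_network,
    }[spec.regime](spec)
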