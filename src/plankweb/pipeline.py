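"""Configured, reproducible pipeline runs.

A :class:`PipelineConfig` (usually loaded from YAML) names the input — either
an OTU table + metadata on disk or a simulation spec — and the stage
parameters.  :func:`run_pipeline` executes the requested stages in dependency
order, writes every artifact under the output directory and records them in a
manifest JSON carrying the config hash and the seed, so identical configs
reproduce byte-identical stochastic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import diversity as div
from . import ncm as ncm_mod
from . import network as net
from . import ordination as ord_mod
from .dnci import dnci as compute_dnci
from .otu import OtuTable, SampleMetadata
from .simulate import CommunitySimSpec, simulate

log = logging.getLogger("plankweb")

STAGES = ("simulate", "diversity", "ordination", "ncm", "dnci", "network", "attack")


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # input: either a simulation spec (CommunitySimSpec kwargs) ...
    simulation: dict | None = None
    # ... or paths to an existing table and its metadata
    otu_table: str | None = None
    metadata: str | None = None
    # ordination: the abundance transform is deliberately explicit — name one
    transform: str | None = None
    n_permutations: int = 999
    # neutral model
    ci_level: float = 0.95
    # dnci
    dnci_permutations: int = 999
    # network
    r_min: float = 0.8
    p_max: float = 0.01
    min_mean_rel_abundance: float = 1e-4
    correction: str | None = None
    # attack
    attack_strategies: list[str] = field(default_factory=lambda: ["betweenness"])
    attack_k: list[int] = field(default_factory=lambda: [10])
    adaptive: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.simulation is None and self.otu_table is None:
            raise ValueError("config needs either a simulation spec or an otu_table path")
        if not 0 < self.r_min <= 1:
            raise ValueError("r_min must lie in (0, 1]")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")
        if not 0 <= self.min_mean_rel_abundance < 1:
            raise ValueError("min_mean_rel_abundance must lie in [0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.n_permutations < 99 or self.dnci_permutations < 99:
            raise ValueError("permutation counts must be >= 99")
        bad = set(self.attack_strategies) - set(net.ATTACK_STRATEGIES)
        if bad:
            raise ValueError(f"unknown attack strategies: {sorted(bad)}")
        if any(k < 0 for k in self.attack_k):
            raise ValueError("attack_k entries must be >= 0")
        if ("ordination" in self.stages) and self.transform is None:
            raise ValueError(
                "ordination requires an explicit abundance transform "
                "(none, log1p or sqrt) in the config"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(base: int, stage: str) -> int:
    """Deterministic substream seed per stage, logged with the stage."""
    digest = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "files": [],
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["files"].extend(str(p.relative_to(outdir)) for p in paths)
        manifest["stages"][stage] = "ok"

    try:
        table, metadata = _load_input(config, outdir, manifest, record)
        groups = None if metadata is None else metadata.frame["region"].reindex(table.sample_ids)

        if "diversity" in config.stages:
            alpha = div.compute_alpha(table)
            alpha_path = outdir / "alpha_diversity.tsv"
            div.alpha_frame(alpha).to_csv(alpha_path, sep="\t")
            dist = div.bray_curtis(table, transform=config.transform or "none")
            dist_path = outdir / "bray_curtis.tsv"
            dist.to_tsv(dist_path)
            paths = [alpha_path, dist_path]
            if metadata is not None:
                corr_path = outdir / "env_correlations.tsv"
                div.env_correlations(alpha, metadata).to_csv(corr_path, sep="\t", index=False)
                paths.append(corr_path)
            record("diversity", *paths)

        if "ordination" in config.stages:
            if groups is None:
                raise RuntimeError("ordination needs sample metadata with regions")
            dist = div.bray_curtis(table, transform=config.transform)
            seed = _stage_seed(config.seed, "ordination")
            log.info("ordination substream seed %d", seed)
            cap_res = ord_mod.cap(dist, groups)
            perm = ord_mod.permanova(dist, groups, config.n_permutations, seed=seed)
            cap_path = outdir / "cap.json"
            cap_path.write_text(json.dumps({
                "delta_sq": cap_res.squared_canonical_correlations.tolist(),
                "m": cap_res.n_pco_axes_used,
                "loo": cap_res.loo_misclassification_rate,
            }, indent=1))
            scores_path = outdir / "cap_scores.tsv"
            np.savetxt(scores_path, cap_res.sample_scores, delimiter="\t")
            perm_path = outdir / "permanova.json"
            perm_path.write_text(json.dumps({
                "F": perm.pseudo_f, "R2": perm.r_squared, "p": perm.p_value,
                "n_perm": perm.n_permutations, "seed": seed,
            }, indent=1))
            record("ordination", cap_path, scores_path, perm_path)

        if "ncm" in config.stages:
            fit = ncm_mod.ncm_fit(table, ci_level=config.ci_level)
            fit_path = outdir / "ncm_fit.json"
            fit_path.write_text(json.dumps(fit.to_json_dict(), indent=1))
            per_otu_path = outdir / "ncm_per_otu.tsv"
            fit.per_otu.to_csv(per_otu_path, sep="\t", index_label="taxon_id")
            record("ncm", fit_path, per_otu_path)

        if "dnci" in config.stages:
            if groups is None:
                raise RuntimeError("dnci needs sample metadata with regions")
            seed = _stage_seed(config.seed, "dnci")
            log.info("dnci substream seed %d", seed)
            results = compute_dnci(table, groups, config.dnci_permutations, seed=seed)
            dnci_path = outdir / "dnci.json"
            payload = [r.to_json_dict() | {"seed": seed} for r in results]
            payload.append({"overall_mean_DNCI": float(np.mean([r.dnci for r in results]))})
            dnci_path.write_text(json.dumps(payload, indent=1))
            e_path = outdir / "dnci_e_values.tsv"
            rows = []
            for r in results:
                for scheme, values in (
                    ("fix_taxa_totals", r.e_dispersal),
                    ("fix_site_totals", r.e_niche),
                    ("fix_both", r.e_both),
                ):
                    rows.extend(
                        {"group_pair": "-".join(r.group_pair), "scheme": scheme,
                         "permutation": i, "E": v}
                        for i, v in enumerate(values)
                    )
            import pandas as pd

            pd.DataFrame(rows).to_csv(e_path, sep="\t", index=False)
            record("dnci", dnci_path, e_path)

        graph = None
        if "network" in config.stages or "attack" in config.stages:
            filtered = net.filter_low_abundance(table, config.min_mean_rel_abundance)
            graph = net.infer_network(
                filtered, r_min=config.r_min, p_max=config.p_max,
                correction=config.correction,
            )

        if "network" in config.stages:
            seed = _stage_seed(config.seed, "network")
            log.info("network substream seed %d", seed)
            edge_path = outdir / "edges.tsv"
            net.write_edge_list(graph, edge_path)
            graphml_path = outdir / "network.graphml"
            net.write_graphml(graph, graphml_path)
            topo_path = outdir / "topology.json"
            topo_path.write_text(json.dumps(net.topology(graph, seed=seed).to_json_dict(), indent=1))
            record("network", edge_path, graphml_path, topo_path)

        if "attack" in config.stages:
            seed = _stage_seed(config.seed, "attack")
            log.info("attack substream seed %d", seed)
            paths = []
            for strategy in config.attack_strategies:
                for k in config.attack_k:
                    traj = net.attack(
                        graph, strategy=strategy, k=k,
                        adaptive=config.adaptive, seed=seed,
                    )
                    path = outdir / f"attack_{strategy}_k{k}.tsv"
                    traj.to_frame().to_csv(path, sep="\t", index=False)
                    paths.append(path)
            record("attack", *paths)
    except Exception as exc:
        failing = next((s for s in config.stages if s not in manifest["stages"]), "?")
        manifest["stages"][failing] = f"failed: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.removeHandler(handler)
        raise RuntimeError(f"stage {failing!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.removeHandler(handler)
    return manifest


def _load_input(config, outdir, manifest, record):
    """Simulate or load the OTU table (+ metadata); record artifacts."""
    if config.simulation is not None:
        spec = CommunitySimSpec(**{**config.simulation, "seed": config.seed})
        result = simulate(spec)
        metadata = None
        if spec.regime == "niche":
            table, truth, metadata = result
        else:
            table, truth = result
        if "simulate" in config.stages:
            table_path = outdir / "otu_table.tsv"
            table.to_tsv(table_path)
            truth_path = outdir / "ground_truth.json"
            truth.to_json(truth_path, taxon_ids=table.taxon_ids)
            paths = [table_path, truth_path]
            if metadata is not None:
                meta_path = outdir / "metadata.tsv"
                metadata.to_tsv(meta_path)
                paths.append(meta_path)
            record("simulate", *paths)
        return table, metadata
    table = OtuTable.from_tsv(config.otu_table)
    metadata = SampleMetadata.from_tsv(config.metadata) if config.metadata else None
    manifest["stages"]["load"] = "ok"
    manifest["inputs"] = [str(config.otu_table)] + (
        [str(config.metadata)] if config.metadata else []
    )
    return table, metadata
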