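"""End-to-end orchestration: filter -> orthogroups -> diversity -> threshold
-> comparison, from a single config, into a reproducible report bundle.

All randomness flows from one root seed through named substreams; the bundle
contains no timestamps, so rerunning an identical config reproduces every
output byte-for-byte, and a machine-readable manifest records the inputs,
seed and parameter hash needed to recompute any number in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import (
    FitConfig,
    compare_groups,
    fit_phylo_lmm,
    fit_poisson_glmm,
    flag_redundant_orthogroups,
    observations_from_abundance,
    posterior_predictive_threshold,
)
from .diversity import (
    build_abundance_matrix,
    orthogroup_diversity,
    species_diversity,
    summarize_diversity,
)
from .orthology import extract_orthogroups
from .seqfilter import filter_repertoire
from .treeio import (
    DEFAULT_CONVENTION,
    LabelConvention,
    parse_gene_tree,
    read_species_tree,
    read_subfamily_registry,
    write_orthogroup_clusters,
)

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline", "summarize_counts"]

logger = logging.getLogger("orthodiv")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class PipelineConfig:
    registry: str  # subfamily -> gene tree TSV
    out_dir: str
    species: list[str]
    species_tree: str | None = None
    fasta: str | None = None
    min_taxa: int = 1
    min_support: float = 0.0
    in_paralogs: bool = True
    outgroup_pattern: str | None = None
    run_threshold: bool = True
    run_compare: bool = False
    iterations: int = 50_000
    thin: int = 10
    burn_in_samples: int = 1000
    q: float = 0.95
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.registry).exists():
            raise PipelineError("validate", f"registry not found: {self.registry}")
        if not self.species:
            raise PipelineError("validate", "species order must be nonempty")
        if self.fasta is not None and not Path(self.fasta).exists():
            raise PipelineError("validate", f"FASTA not found: {self.fasta}")
        if self.run_compare:
            if self.species_tree is None:
                raise PipelineError(
                    "validate", "compare stage enabled but no species tree configured"
                )
            if not Path(self.species_tree).exists():
                raise PipelineError(
                    "validate", f"species tree not found: {self.species_tree}"
                )

    def fit_config(self, seed: int) -> FitConfig:
        return FitConfig(
            iterations=self.iterations,
            thin=self.thin,
            burn_in_samples=self.burn_in_samples,
            q=self.q,
            seed=seed,
        )


@dataclass
class PipelineResult:
    out_dir: Path
    n_orthogroups: int
    pooled_diversity: pd.DataFrame
    threshold: int | None
    mean_upper: float | None
    comparison: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _substream_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kw)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle to ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _substream_seeds(config.seed, 4)
    convention = LabelConvention(outgroup_pattern=config.outgroup_pattern)

    if config.fasta is not None:
        try:
            _, report = filter_repertoire(
                config.fasta, out / "intact.fasta", out / "filter_report.tsv"
            )
            logger.info("seqfilter: %s", report.to_dict("records"))
        except Exception as exc:
            raise PipelineError("filter", f"{config.fasta}: {exc}") from exc

    try:
        registry = read_subfamily_registry(config.registry)
    except Exception as exc:
        raise PipelineError("registry", str(exc)) from exc

    ogsets = []
    for subfam, tree_path in registry.items():
        try:
            gt = parse_gene_tree(
                tree_path.read_text(), convention=convention, subfamily=subfam
            )
            ogsets.append(
                extract_orthogroups(
                    gt,
                    min_taxa=config.min_taxa,
                    min_support=config.min_support,
                    in_paralogs=config.in_paralogs,
                )
            )
        except Exception as exc:
            raise PipelineError("orthogroups", f"{tree_path}: {exc}") from exc

    write_orthogroup_clusters(ogsets, out / "orthogroup_clusters.tsv")

    try:
        matrix = build_abundance_matrix(ogsets, config.species)
        matrix.to_tsv(out / "abundance_matrix.tsv")
        per_og = orthogroup_diversity(matrix) if len(matrix.table) else pd.DataFrame()
        pooled = species_diversity(matrix, scope="pooled") if len(matrix.table) else pd.DataFrame(columns=["species", "H"])
        by_sub = species_diversity(matrix, scope="by_subfamily") if len(matrix.table) else pd.DataFrame(columns=["subfamily", "species", "H"])
        if len(per_og):
            _write_tsv(per_og, out / "diversity_orthogroup.tsv")
        _write_tsv(pooled, out / "diversity_species_pooled.tsv")
        _write_tsv(by_sub, out / "diversity_subfamily_by_species.tsv")
        if len(per_og) or len(pooled) or len(by_sub):
            summary = summarize_diversity(pooled, by_sub, per_og)
            for name, df in summary.items():
                _write_tsv(df, out / f"summary_{name}.tsv")
    except Exception as exc:
        raise PipelineError("diversity", str(exc)) from exc

    threshold = mean_upper = None
    if config.run_threshold and len(matrix.table):
        try:
            obs = observations_from_abundance(matrix)
            samples = fit_poisson_glmm(obs, config.fit_config(seeds[0]))
            th = posterior_predictive_threshold(samples, seed=seeds[1])
            threshold, mean_upper = th.threshold, th.mean_upper
            _write_tsv(samples.draws, out / "posterior_counts.tsv")
            pd.DataFrame(
                [
                    {
                        "mean_upper": th.mean_upper,
                        "sd_upper": th.sd_upper,
                        "pooled_upper": th.pooled_upper,
                        "threshold": th.threshold,
                        "q": th.q,
                    }
                ]
            ).to_csv(out / "threshold_report.tsv", sep="\t", index=False, float_format="%.10g")
            flags = flag_redundant_orthogroups(matrix, th.threshold)
            _write_tsv(flags, out / "redundant_orthogroups.tsv")
        except Exception as exc:
            raise PipelineError("threshold", str(exc)) from exc

    comparison = None
    if config.run_compare and len(matrix.table):
        try:
            sp_tree = read_species_tree(Path(config.species_tree))
            lmm = fit_phylo_lmm(by_sub, sp_tree, config.fit_config(seeds[2]))
            comparison = compare_groups(lmm, groups="species", interval=0.5)
            _write_tsv(comparison, out / "species_comparison.tsv")
            comparison_sub = compare_groups(lmm, groups="subfamily", interval=0.5)
            _write_tsv(comparison_sub, out / "subfamily_comparison.tsv")
            _write_tsv(
                lmm.draws[["mu", "sigma2_a", "sigma2_b", "sigma2_eps"] + lmm.species_effect_columns()],
                out / "posterior_diversity.tsv",
            )
        except Exception as exc:
            raise PipelineError("compare", str(exc)) from exc

    cfg_dict = asdict(config)
    manifest = {
        "orthodiv_version": __version__,
        "config": cfg_dict,
        "parameter_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "substream_seeds": seeds,
        "inputs": sorted(str(p) for p in read_subfamily_registry(config.registry).values()),
        "n_orthogroups": int(len(matrix.table)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        out_dir=out,
        n_orthogroups=int(len(matrix.table)),
        pooled_diversity=pooled,
        threshold=threshold,
        mean_upper=mean_upper,
        comparison=comparison,
        manifest=manifest,
    )


def summarize_counts(
    clusters_path: str | Path,
    convention: LabelConvention = DEFAULT_CONVENTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species gene totals and per-(subfamily, species) counts from a
    cluster-list file. The grand total equals the number of cluster members."""
    from .treeio import read_orthogroup_clusters

    rows = read_orthogroup_clusters(clusters_path)
    totals: dict[str, int] = {}
    per_sub: dict[tuple[str, str], int] = {}
    for subfam, _og, members in rows:
        for member in members:
            sp, _ = convention.split(member)
            totals[sp] = totals.get(sp, 0) + 1
            per_sub[(subfam, sp)] = per_sub.get((subfam, sp), 0) + 1
    totals_df = pd.DataFrame(
        [{"species": sp, "genes": n} for sp, n in sorted(totals.items())],
        columns=["species", "genes"],
    )
    per_sub_df = pd.DataFrame(
        [
            {"subfamily": sf, "species": sp, "genes": n}
            for (sf, sp), n in sorted(per_sub.items())
        ],
        columns=["subfamily", "species", "genes"],
    )
    return totals_df, per_sub_df
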