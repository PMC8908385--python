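"""End-to-end orchestration: simulate or load a genotype dataset, recode it
under each assumed ploidy, estimate dosage-corrected frequencies, compute
diversity, pairwise differentiation, AMOVAs per declared hierarchy and a
PCA, and write all tables plus a manifest with seeds and content hashes.

Hierarchies are declared, not inferred: groupings typically come from an
external clustering (species assignment at K = 2, north/south clusters
within species, morphotypes).  ``hierarchy_from_ancestry`` converts a
chosen-K ancestry table into such a declaration by max-ancestry assignment,
and ``max_ancestry_mismatch_filter`` flags individuals whose own assignment
disagrees with their population's (the generic form of excluding stray
individuals of the other species before within-species analyses).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio, popstats
from .ploidy import recode_dataset
from .simulate import SimConfig, simulate_dataset

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "hierarchy_from_ancestry",
    "max_ancestry_mismatch_filter",
]

logger = logging.getLogger("mixopop")


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None
    genotypes_path: str | None = None
    meta_path: str | None = None
    assumed_ploidies: tuple[int, ...] = (2, 4, 8)
    replicates: int = 10
    seed: int = 0
    hierarchies: dict[str, dict[str, str]] = field(default_factory=dict)
    outdir: str = "mixopop_out"

    def validate(self) -> None:
        if not self.assumed_ploidies:
            raise ValueError("need at least one assumed ploidy")
        if any(m not in (2, 4, 8) for m in self.assumed_ploidies):
            raise ValueError(f"assumed ploidies must be among (2, 4, 8): {self.assumed_ploidies}")
        if self.sim is None and self.genotypes_path is None:
            raise ValueError("either a simulation config or a genotype path is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**{**raw, "sim": SimConfig(**sim) if sim else None})
        if "assumed_ploidies" in raw:
            cfg.assumed_ploidies = tuple(raw["assumed_ploidies"])
        return cfg


def hierarchy_from_ancestry(
    ancestry: pd.DataFrame, name: str = "ancestry"
) -> popstats.Hierarchy:
    """Max-ancestry assignment of each population to a cluster column."""
    group_of = {pop: str(ancestry.loc[pop].idxmax()) for pop in ancestry.index}
    return popstats.Hierarchy(group_of=group_of, name=name)


def max_ancestry_mismatch_filter(
    q: pd.DataFrame, population_of: dict[str, str], threshold: float = 0.5
) -> list[str]:
    """Individuals whose max-ancestry cluster disagrees with their
    population's majority cluster (with max ancestry above ``threshold``):
    candidates for exclusion before within-group analyses."""
    assign = q.idxmax(axis=1)
    strength = q.max(axis=1)
    frame = pd.DataFrame(
        {"cluster": assign, "strength": strength,
         "population": [population_of[i] for i in q.index]}
    )
    pop_majority = frame.groupby("population")["cluster"].agg(
        lambda s: s.value_counts().idxmax()
    )
    flagged = [
        ind
        for ind, row in frame.iterrows()
        if row["strength"] >= threshold and row["cluster"] != pop_majority[row["population"]]
    ]
    return flagged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("%s done in %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to
    ``outdir/manifest.json``)."""
    config.validate()
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[mixopop] %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    t0 = time.perf_counter()

    if config.sim is not None:
        sim = simulate_dataset(config.sim)
        ds, meta = dataio.dataset_from_simulation(sim)
        dataio.write_genotypes(ds, outdir / "genotypes.csv")
        dataio.write_population_meta(meta, outdir / "populations.csv")
        with open(outdir / "cp_sequences.fasta", "w") as fh:
            for ind in sim.individuals:
                fh.write(
                    f">{ind.individual_id} location={ind.population_code} "
                    f"haplotype={ind.cp_haplotype_id}\n{ind.cp_sequence}\n"
                )
        truth = {
            "seed": config.sim.seed,
            "fct_sim": config.sim.fct_sim,
            "fsc_sim": config.sim.fsc_sim,
            "species_divergence": config.sim.species_divergence,
            "ploidy_by_individual": {
                ind.individual_id: ind.ploidy for ind in sim.individuals
            },
            "hybrids": [ind.individual_id for ind in sim.individuals if ind.hybrid],
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
        outputs["genotypes"] = "genotypes.csv"
        outputs["populations"] = "populations.csv"
        outputs["cp_sequences"] = "cp_sequences.fasta"
        outputs["truth"] = "truth.json"
        t0 = _stage("simulate", t0)
    else:
        meta = (
            dataio.read_population_meta(config.meta_path) if config.meta_path else None
        )
        ds = dataio.read_genotypes(config.genotypes_path, meta=meta)
        t0 = _stage("load", t0)

    hierarchies = {
        name: popstats.Hierarchy(group_of=mapping, name=name)
        for name, mapping in config.hierarchies.items()
    }
    if not hierarchies and meta is not None:
        clusters = {p.population_code: p.cluster_label for p in meta}
        if all(v is not None for v in clusters.values()):
            hierarchies["clusters"] = popstats.Hierarchy(group_of=clusters, name="clusters")
        species = {p.population_code: p.species_label for p in meta}
        if all(species.values()):
            hierarchies["species"] = popstats.Hierarchy(group_of=species, name="species")

    cross_rows = []
    for m in config.assumed_ploidies:
        tag = f"{m}x"
        coding = recode_dataset(ds, m, seed=config.seed)
        dataio.export_structure(ds, coding, outdir / f"structure_input_{tag}.str")
        outputs[f"structure_input_{tag}"] = f"structure_input_{tag}.str"

        freqs = popstats.population_frequencies(ds, coding)
        div = popstats.diversity_table(ds, coding, freqs)
        div.to_csv(outdir / f"diversity_{tag}.csv", index=False)
        outputs[f"diversity_{tag}"] = f"diversity_{tag}.csv"
        t0 = _stage(f"diversity {tag}", t0)

        for stat in ("Gst", "JostD"):
            pw = popstats.pairwise_differentiation(freqs, statistic=stat)
            pw.values.to_csv(outdir / f"pairwise_{stat.lower()}_{tag}.csv")
            outputs[f"pairwise_{stat.lower()}_{tag}"] = f"pairwise_{stat.lower()}_{tag}.csv"
        t0 = _stage(f"pairwise {tag}", t0)

        for name, hierarchy in hierarchies.items():
            try:
                result = popstats.amova(
                    ds, coding, hierarchy, replicates=config.replicates, seed=config.seed
                )
            except ValueError as exc:
                logger.warning("AMOVA %s at %s skipped: %s", name, tag, exc)
                continue
            result.to_frame().to_csv(outdir / f"amova_{name}_{tag}.csv", index=False)
            outputs[f"amova_{name}_{tag}"] = f"amova_{name}_{tag}.csv"
            row = {"hierarchy": name, "assumed_ploidy": m}
            row.update(result.f_stats)
            cross_rows.append(row)
        t0 = _stage(f"amova {tag}", t0)

        pca = popstats.pca_genotypes(ds, coding)
        pca_frame = pca.coordinates.copy()
        pca_frame.insert(0, "individual_id", pca_frame.index)
        pca_frame.to_csv(outdir / f"pca_{tag}.csv", index=False)
        outputs[f"pca_{tag}"] = f"pca_{tag}.csv"
        t0 = _stage(f"pca {tag}", t0)

    if cross_rows:
        cross = pd.DataFrame(cross_rows)
        cross.to_csv(outdir / "fstats_by_ploidy.csv", index=False)
        outputs["fstats_by_ploidy"] = "fstats_by_ploidy.csv"

    manifest = {
        "seed": config.seed,
        "replicates": config.replicates,
        "assumed_ploidies": list(config.assumed_ploidies),
        "sim": dataclasses.asdict(config.sim) if config.sim else None,
        "outputs": {
            key: {"path": rel, "sha256": _sha256(outdir / rel)}
            for key, rel in outputs.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(outputs), outdir)
    return manifest
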