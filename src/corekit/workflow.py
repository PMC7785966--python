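"""End-to-end pipeline: ingest/simulate -> diversity -> structure -> LDSS
ladder -> core selection -> evaluation, with a reproducibility manifest.

The core-selection rule formalizes the usual trade-off "mainly genetic
diversity, supplemented by metabolite content": among the ladder's
collections whose allele retention rate Ra meets a threshold (default 90%),
the smallest collection is preferred, with ties broken by the higher total
metabolite mean.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .diversity import diversity_summary
from .evaluation import evaluate, random_baseline
from .io import (
    GenotypeMatrix,
    MetaboliteTable,
    write_genotypes,
    write_metabolites,
    write_populations,
    write_report,
    write_tree_newick,
)
from .ldss import DEFAULT_RATIOS, ladder
from .structure import amova, genetic_distance, pairwise_phipt, pcoa, upgma
from .synthetic import SyntheticConfig, generate, study_like_config

logger = logging.getLogger("corekit")


def select_core(table: pd.DataFrame, ra_threshold: float = 90.0) -> str:
    """Pick the best collection from a ladder summary table.

    Among non-original rows with ``ra >= ra_threshold`` choose the smallest
    size; break ties by the larger total metabolite mean.  Falls back to the
    highest-Ra collection when none qualifies.
    """
    rows = table[table["ratio"] < 1.0]
    if rows.empty:
        raise ValueError("ladder table has no candidate collections")
    qualified = rows[rows["ra"] >= ra_threshold]
    if qualified.empty:
        logger.warning("no collection reaches Ra >= %.1f%%; falling back to max Ra", ra_threshold)
        return str(rows.sort_values(["ra", "mean_total"], ascending=False).iloc[0]["name"])
    best = qualified.sort_values(
        ["size", "mean_total"], ascending=[True, False], kind="mergesort"
    ).iloc[0]
    return str(best["name"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 715
    simulate: bool = True
    synthetic: SyntheticConfig | None = None
    genotypes: GenotypeMatrix | None = None
    metabolites: MetaboliteTable | None = None
    populations: dict[str, str] | None = None
    ratios: Sequence[float] = DEFAULT_RATIOS
    sizes: Sequence[int] | None = None
    distance_kind: str = "band_sq_euclidean"
    ra_threshold: float = 90.0
    n_permutations: int = 0
    baseline_reps: int = 0


def run_all(config: RunConfig) -> Path:
    """Run the whole analysis and write every artifact under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}, "outputs": {}}

    stage = "inputs"
    try:
        if config.simulate and config.genotypes is None:
            syn = config.synthetic or study_like_config(seed=config.seed)
            panel = generate(syn, seed=config.seed)
            gm, met, pops = panel.genotypes, panel.metabolites, panel.populations
            write_genotypes(gm, out / "genotypes.csv", "genalex_csv", pops)
            write_metabolites(met, out / "metabolites.csv")
            write_populations(pops, out / "populations.tsv")
            write_report(panel.ground_truth, out / "ground_truth.json")
            manifest["stages"]["simulate"] = {
                "population_sizes": list(syn.population_sizes),
                "n_loci": syn.n_loci,
                "fst": syn.fst,
            }
        else:
            if config.genotypes is None or config.metabolites is None:
                raise ValueError("run_all needs genotypes+metabolites or simulate=True")
            gm, met, pops = config.genotypes, config.metabolites, config.populations or {}

        stage = "diversity"
        summary = diversity_summary(gm)
        write_report(summary, out / "diversity.json")

        stage = "structure"
        dist = genetic_distance(gm, config.distance_kind)
        tree = upgma(dist)
        write_tree_newick(tree, out / "upgma.nwk")
        ordination = pcoa(dist, n_axes=3)
        frame = ordination.to_frame()
        frame.to_csv(out / "pcoa.tsv", sep="\t", index=False)
        structure_report: dict = {
            "pcoa_percent_explained": ordination.percent_explained.tolist()
        }
        if pops:
            res = amova(dist, pops, n_permutations=config.n_permutations, seed=config.seed)
            structure_report["amova"] = res.to_dict()
            structure_report["pairwise_phipt"] = pairwise_phipt(dist, pops).to_dict()
        write_report(structure_report, out / "structure.json")

        stage = "ldss"
        lad = ladder(gm, met, ratios=config.ratios, sizes=config.sizes, distance=dist)
        lad.table.to_csv(out / "ladder.tsv", sep="\t", index=False)
        lad.core.log_frame().to_csv(out / "removal_log.tsv", sep="\t", index=False)
        for ratio in sorted(lad.core.checkpoints, reverse=True):
            if ratio >= 1.0:
                continue
            name = f"{round(ratio * 100):g}CC"
            (out / f"core_{name}.txt").write_text(
                "\n".join(lad.core.checkpoints[ratio]) + "\n"
            )

        stage = "selection"
        chosen = select_core(lad.table, config.ra_threshold)
        ratio = float(lad.table.loc[lad.table["name"] == chosen, "ratio"].iloc[0])
        core_ids = lad.core.checkpoints[ratio]
        manifest["stages"]["selection"] = {"chosen": chosen, "ratio": ratio, "size": len(core_ids)}

        stage = "evaluation"
        report = evaluate(gm, met, core_ids, distance=dist)
        write_report(report, out / "evaluation.json")
        if config.baseline_reps > 0:
            base = random_baseline(gm, met, len(core_ids), config.baseline_reps, config.seed)
            write_report({"size": base.size, "reps": base.reps, "summary": base.summary},
                         out / "baseline.json")
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete; %d outputs in %s", len(manifest["outputs"]), out)
    return out
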