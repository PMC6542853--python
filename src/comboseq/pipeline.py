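"""End-to-end orchestration: simulate (or load) -> DE -> combination analysis.

Runs the four contrasts (A vs vehicle, B vs vehicle, combo vs vehicle,
combo vs B) from one configuration, writes every table as TSV plus a
machine-readable ``summary.json``, and returns a report whose counts are all
recomputable from the written artifacts. Identical configuration and seed
give a byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .additivity import (
    attenuation,
    classify_concordance,
    partition_sets,
    standard_additivity_fits,
)
from .de import NBFactorialModel, select_de
from .io import (
    AnalysisConfig,
    CountMatrix,
    ValidationError,
    read_counts,
    read_design,
    write_results,
)
from .simulate import SimulationParams, simulate_dataset

logger = logging.getLogger("comboseq")

CONTRASTS = (
    ("TRT_A", "VEHICLE"),
    ("TRT_B", "VEHICLE"),
    ("COMBO", "VEHICLE"),
    ("COMBO", "TRT_B"),
)


@dataclass(frozen=True)
class PipelineReport:
    """Machine-readable pipeline outcome; every count is recomputable from
    the written TSVs."""

    config: dict
    de_counts: dict
    venn: dict
    concordance: dict
    fits: dict
    attenuation: dict
    manifest: list
    seed: int
    version: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _de_count_summary(table: pd.DataFrame, alpha: float) -> dict:
    padj = table["padj"].to_numpy(float)
    de = np.isfinite(padj) & (padj < alpha)
    lfc = table["log2fc"].to_numpy(float)
    induced = int((de & (lfc > 0)).sum())
    repressed = int((de & (lfc < 0)).sum())
    return {"total": int(de.sum()), "induced": induced, "repressed": repressed}


def run_pipeline(
    config: AnalysisConfig,
    sim_params: Optional[SimulationParams] = None,
    counts_path=None,
    design_path=None,
) -> PipelineReport:
    """Execute all stages in order and write the report.

    Exactly one input source must be given: simulation parameters, or paths
    to a counts TSV and a design TSV.
    """
    have_sim = sim_params is not None
    have_real = counts_path is not None or design_path is not None
    if have_sim == have_real:
        raise ValidationError(
            "provide either simulation parameters or counts+design paths, not both"
        )

    tables: dict = {}
    config_echo = dataclasses.asdict(config)
    if have_sim:
        truth, cm, design = simulate_dataset(sim_params)
        logger.info(
            "stage simulate: %d genes x %d samples (seed %d)",
            cm.n_genes, cm.n_samples, sim_params.seed,
        )
        tables["truth"] = truth
        tables["counts"] = cm.to_frame().reset_index(names="gene_id")
        tables["design"] = design
        sp = dataclasses.asdict(sim_params)
        if sp["libsize_factors"] is not None:
            sp["libsize_factors"] = [float(x) for x in sp["libsize_factors"]]
        config_echo["simulation"] = sp
    else:
        if counts_path is None or design_path is None:
            raise ValidationError("both --counts and --design are required for real data")
        cm = read_counts(counts_path)
        design = read_design(design_path)
        logger.info("stage load: %d genes x %d samples", cm.n_genes, cm.n_samples)

    model = NBFactorialModel(cm, design, min_total_count=config.min_total_count)
    res = model.fit()
    logger.info(
        "stage de: fitted %d genes, %d tested (seed %d)",
        cm.n_genes, int(res.tested.sum()), config.seed,
    )

    contrast_tables = {}
    de_counts = {}
    for cond, ref in CONTRASTS:
        name = f"{cond}_vs_{ref}"
        table = res.contrast(cond, ref)
        contrast_tables[name] = table
        tables[f"contrast_{name}"] = table
        de_counts[name] = _de_count_summary(table, config.alpha)

    res_A = contrast_tables["TRT_A_vs_VEHICLE"]
    res_B = contrast_tables["TRT_B_vs_VEHICLE"]
    res_AB = contrast_tables["COMBO_vs_VEHICLE"]
    res_AB_vs_B = contrast_tables["COMBO_vs_TRT_B"]
    set_A = select_de(res_A, config.alpha)
    set_B = select_de(res_B, config.alpha)
    set_AB = select_de(res_AB, config.alpha)

    venn = partition_sets(set_A, set_B, set_AB)
    logger.info("stage additivity: |A|=%d |B|=%d |AB|=%d", len(set_A), len(set_B), len(set_AB))

    lfcA = res_A.set_index("gene_id")["log2fc"]
    lfcB = res_B.set_index("gene_id")["log2fc"]
    concordance: dict = {}
    if venn.commonAB:
        concordance = classify_concordance(venn.commonAB, lfcA, lfcB).counts()

    fits = standard_additivity_fits(res_A, res_B, res_AB, set_A, set_B, set_AB)
    observed = res_AB.set_index("gene_id")["log2fc"]
    expected = lfcA + lfcB
    subsets = {
        "union_singles": set_A.genes | set_B.genes,
        "common": set_A.genes & set_B.genes,
        "combo_only": set_AB.genes - (set_A.genes | set_B.genes),
    }
    for name, subset in subsets.items():
        genes = sorted(subset)
        tables[f"scatter_{name}"] = pd.DataFrame(
            {
                "gene_id": genes,
                "expected": expected.loc[genes].to_numpy(),
                "observed": observed.loc[genes].to_numpy(),
            }
        )

    atten = attenuation(set_B, res_B, res_AB_vs_B, alpha=config.alpha)
    tables["attenuated_genes"] = pd.DataFrame({"gene_id": sorted(atten.attenuated)})

    summary = {
        "config": config_echo,
        "de_counts": de_counts,
        "venn": venn.counts(),
        "concordance": concordance,
        "fits": {k: v.to_dict() for k, v in fits.items()},
        "attenuation": atten.counts(),
        "seed": config.seed,
        "version": __version__,
    }
    manifest = write_results(tables, summary, config.output_dir)
    manifest_rel = [Path(p).name for p in manifest]
    logger.info("stage write: %d files in %s", len(manifest), config.output_dir)

    return PipelineReport(
        config=config_echo,
        de_counts=de_counts,
        venn=venn.counts(),
        concordance=concordance,
        fits={k: v.to_dict() for k, v in fits.items()},
        attenuation=atten.counts(),
        manifest=manifest_rel,
        seed=config.seed,
        version=__version__,
    )
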