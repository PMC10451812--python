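"""End-to-end orchestration: ingest -> transitions -> regions -> abratio ->
domain strength -> genes -> boundaries, from one YAML/dict config.

Each stage writes stable filenames under the output directory and the run
ends with a manifest (JSON) listing per-stage inputs, parameters and output
checksums, so re-runs with an unchanged config can be verified byte-for-byte
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .abratio import ab_ratio_by_subcompartment, ab_ratio_frame, interchromosomal_ab_scores
from .boundaries import (
    boundary_gene_profile,
    inside_outside_domain_counts,
    signal_by_subcompartment,
)
from .contacts import ContactMap, read_contact_dump
from .domains import compute_background_decay, merge_domain_calls, score_domains
from .genes import (
    adjust_bh,
    classify_genes,
    density_by_subcompartment,
    gap_lengths,
    gene_density,
    region_enrichment,
)
from .genome import BinnedGenome
from .labels import derive_compartment_mask
from .transitions import region_sets, repositioning_proportion, transition_counts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = (
    "ingest", "transitions", "regions", "abratio",
    "domstrength", "genes", "boundaries",
)


@dataclass
class RunConfig:
    """Input paths and parameters of a full run.

    ``labels`` maps cell-type name -> subcompartment BED; ``intra`` maps
    chromosome -> dump path; ``inter`` maps "chrA,chrB" -> dump path.
    """

    chrom_lengths: dict[str, int]
    cell_types: list[str]
    labels: dict[str, str]
    intra: dict[str, str]
    inter: dict[str, str]
    domains_5kb: str
    domains_10kb: str
    tads: str
    genes_bed: str
    fpkm: str
    housekeeping: str
    signal: dict[str, str] = field(default_factory=dict)
    resolution: int = 50_000
    reference: str | None = None
    outdir: str = "results"
    seed: int = 0
    exclude_sex_chroms: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            k: getattr(self, k)
            for k in self.__dataclass_fields__  # type: ignore[attr-defined]
        }

    def validate_paths(self) -> None:
        paths = (
            list(self.labels.values()) + list(self.intra.values())
            + list(self.inter.values())
            + [self.domains_5kb, self.domains_10kb, self.tads,
               self.genes_bed, self.fpkm, self.housekeeping]
            + list(self.signal.values())
        )
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing input file(s): {missing}"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage and return (and write) the results manifest.

    Raises at the first failing stage, naming it; outputs written before the
    failure are flagged stale in the partial manifest left on disk.
    """
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    genome = BinnedGenome.from_chromsizes(
        config.chrom_lengths, config.resolution,
        exclude_sex_chroms=config.exclude_sex_chroms,
    )
    reference = config.reference or config.cell_types[0]
    outputs_so_far: list[Path] = []

    def finish_stage(name: str, outputs: list[Path], params: dict) -> None:
        manifest["stages"][name] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "parameters": params,
            "status": "complete",
        }
        outputs_so_far.extend(outputs)
        _write_manifest(manifest, out)

    try:
        # -- ingest -------------------------------------------------------
        stage = "ingest"
        labelings = {
            ct: aio.read_subcompartment_bed(config.labels[ct], genome, ct)
            for ct in config.cell_types
        }
        intra = ContactMap.combine(
            [
                read_contact_dump(p, genome, "intra", chrom)
                for chrom, p in config.intra.items()
            ]
        )
        inter = ContactMap.combine(
            [
                read_contact_dump(p, genome, "inter", *key.split(","))
                for key, p in config.inter.items()
            ]
        )
        d5 = aio.read_domain_bedpe(config.domains_5kb, 5000)
        d10 = aio.read_domain_bedpe(config.domains_10kb, 10000)
        tads = aio.read_tad_bed(config.tads)
        hk = aio.read_housekeeping_tsv(config.housekeeping)
        genes = aio.read_gene_bed(config.genes_bed, housekeeping=hk)
        expr = aio.read_fpkm_tsv(config.fpkm)
        tracks = {
            mark: aio.read_bedgraph(p, genome, mark)
            for mark, p in config.signal.items()
        }
        finish_stage(stage, [], {"n_bins": genome.n_bins})

        # -- transitions --------------------------------------------------
        stage = "transitions"
        trans_outputs = []
        trans_summary = []
        for ct in config.cell_types:
            if ct == reference:
                continue
            table = transition_counts(labelings[reference], labelings[ct])
            p = out / f"transitions.{reference}_to_{ct}.tsv"
            table.to_frame().to_csv(p, sep="\t")
            pl = out / f"transitions.{reference}_to_{ct}.long.tsv"
            table.to_long().to_csv(pl, sep="\t", index=False)
            trans_outputs += [p, pl]
            trans_summary.append(
                dict(src=reference, dst=ct,
                     repositioning=repositioning_proportion(table))
            )
        psum = out / "repositioning.tsv"
        pd.DataFrame(trans_summary).to_csv(psum, sep="\t", index=False)
        trans_outputs.append(psum)
        finish_stage(stage, trans_outputs, {"reference": reference})

        # -- regions ------------------------------------------------------
        stage = "regions"
        regions = region_sets(list(labelings.values()))
        region_outputs = []
        for name, rs in regions.items():
            p = out / f"{name}.bed"
            rs.to_bed(p)
            region_outputs.append(p)
        finish_stage(stage, region_outputs, {})

        # -- abratio ------------------------------------------------------
        stage = "abratio"
        mask = derive_compartment_mask(labelings[reference])
        scores = interchromosomal_ab_scores(inter, mask)
        results = ab_ratio_by_subcompartment(scores, labelings[reference])
        p = out / "ab_ratio.tsv"
        ab_ratio_frame(results).to_csv(p, sep="\t", index=False)
        finish_stage(stage, [p], {"reference": reference})

        # -- domstrength --------------------------------------------------
        stage = "domstrength"
        merged = merge_domain_calls(d5, d10)
        background = compute_background_decay(intra, mask)
        region_bins = {
            "common_A1": regions["common_A1"].bins,
            "variable_A1": regions[f"variable_A1.{reference}"].bins,
        }
        scored = score_domains(
            merged, intra, background, labelings[reference], region_bins
        )
        p = out / "domain_strength.tsv"
        scored.to_csv(p, sep="\t", index=False)
        finish_stage(
            stage, [p],
            {"n_domains": len(merged), "n_b_blocks": background.n_blocks},
        )

        # -- genes --------------------------------------------------------
        stage = "genes"
        classes = classify_genes(expr, genes)
        gene_outputs = []
        density_rows = []
        for ct in config.cell_types:
            active = genes.subset(classes.genes_of("active", ct))
            density_rows.append(
                dict(cell_type=ct, klass="active",
                     **density_by_subcompartment(active, labelings[ct]).to_dict())
            )
        pdens = out / "gene_density.tsv"
        pd.DataFrame(density_rows).to_csv(pdens, sep="\t", index=False)
        gene_outputs.append(pdens)
        hk_genes = genes.subset(classes.genes_of("housekeeping"))
        enr = []
        for ct in config.cell_types:
            spec = genes.subset(classes.genes_of("specific", ct))
            if len(spec) == 0:
                continue
            var_key = f"variable_A1.{ct}"
            enr.append(
                region_enrichment(
                    spec, hk_genes, regions[var_key], regions["common_A1"],
                    description=f"specific({ct}) vs housekeeping, "
                                f"variable vs common A1",
                )
            )
        if enr:
            adjust_bh(enr)
        penr = out / "enrichment.tsv"
        pd.DataFrame(
            [
                dict(description=e.description, odds_ratio=e.odds_ratio,
                     p_value=e.p_value, q_value=e.p_adjusted,
                     **{f"n{i}{j}": int(e.table[i, j])
                        for i in (0, 1) for j in (0, 1)})
                for e in enr
            ]
        ).to_csv(penr, sep="\t", index=False)
        gene_outputs.append(penr)
        gaps_rows = []
        active_ref = genes.subset(classes.genes_of("active", reference))
        for name in ("common_A1", f"variable_A1.{reference}"):
            gl = gap_lengths(active_ref, regions[name])
            gaps_rows.append(
                dict(region=name, n=gl["n"], median=gl["median"],
                     q1=gl["q1"], q3=gl["q3"])
            )
        pgaps = out / "gap_lengths.tsv"
        pd.DataFrame(gaps_rows).to_csv(pgaps, sep="\t", index=False)
        gene_outputs.append(pgaps)
        finish_stage(stage, gene_outputs, {})

        # -- boundaries ---------------------------------------------------
        stage = "boundaries"
        bnd_outputs = []
        chrom_lengths = dict(zip(genome.chroms, genome.lengths))
        for klass, table in (
            ("housekeeping", hk_genes),
            ("active", active_ref),
        ):
            prof = boundary_gene_profile(
                tads.boundaries(genome), table, chrom_lengths,
                bin_width=config.resolution, gene_class=klass,
            )
            p = out / f"boundary_profile.{klass}.tsv"
            prof.to_frame().to_csv(p, sep="\t", index=False)
            bnd_outputs.append(p)
        io_rows = []
        for name in ("common_A1", f"variable_A1.{reference}"):
            for klass, table in (
                ("housekeeping", hk_genes), ("active", active_ref)
            ):
                c = inside_outside_domain_counts(
                    table, merged, regions[name], gene_class=klass
                )
                io_rows.append(
                    dict(region=name, gene_class=klass, inside=c.inside,
                         outside=c.outside, inside_bp=c.inside_bp,
                         outside_bp=c.outside_bp)
                )
        pio = out / "inside_outside.tsv"
        pd.DataFrame(io_rows).to_csv(pio, sep="\t", index=False)
        bnd_outputs.append(pio)
        for mark, track in tracks.items():
            p = out / f"signal_by_subcompartment.{mark}.tsv"
            signal_by_subcompartment(track, labelings[reference]).to_csv(
                p, sep="\t"
            )
            bnd_outputs.append(p)
        finish_stage(stage, bnd_outputs, {})
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        for st in manifest["stages"].values():
            st["status"] = "stale"
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict[str, Any], outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
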