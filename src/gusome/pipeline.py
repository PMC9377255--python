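"""Stage orchestration: chains discovery, abundance, proteomics, rates and
association over files on disk, writing one TSV/JSON per product plus a
machine-readable run manifest (config, seed, input checksums, stage
status).  Rerunning with the same inputs, config and seed reproduces
byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import abundance as ab
from . import diversity as dv
from . import kinetics as kn
from . import proteomics as pq
from .config import PipelineConfig, get_logger
from .discovery import clusters_to_newick, discover
from .io import (
    read_metadata,
    read_protein_fasta,
    read_representatives,
    read_table,
    sha256_of,
    write_table,
)
from .types import GusCluster

COORD_NOTE = "coordinates 1-based, intervals closed"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _clusters_from_table(path: Path) -> list[GusCluster]:
    df = read_table(path, required=("cluster_id", "representative_id", "member_ids",
                                    "gus_class"))
    return [
        GusCluster(
            cluster_id=row["cluster_id"],
            representative_id=row["representative_id"],
            member_ids=tuple(row["member_ids"].split(";")),
            gus_class=row["gus_class"],
            class_flag=row.get("class_flag") or "",
            taxonomy=row.get("taxonomy") or "unassigned",
            taxonomy_identity=float(row.get("taxonomy_identity") or 0.0),
        )
        for _, row in df.iterrows()
    ]


def run_pipeline(
    inputs: Mapping[str, str | Path],
    outdir: str | Path,
    config: PipelineConfig | None = None,
    stages: tuple[str, ...] = ("discover", "abundance", "proteomics", "rates",
                               "associate"),
    write_newick: bool = False,
    verbose: bool = False,
) -> dict:
    """Run the requested stages in order and write the result bundle.

    ``inputs`` names the files each stage needs: ``catalog``,
    ``representatives_fasta``, ``representatives_annot``, ``counts``,
    ``peptides``, ``timecourses``, ``metadata``.  Any stage failure
    aborts with the stage name; the manifest marks whatever completed.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = get_logger("gusome.pipeline", verbose)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "complete": False,
    }
    for name, path in inputs.items():
        p = Path(path)
        manifest["inputs"][name] = {
            "path": str(p),
            "sha256": sha256_of(p) if p.exists() else None,
        }

    def _require(*names: str) -> list[Path]:
        out = []
        for n in names:
            if n not in inputs or not Path(inputs[n]).exists():
                raise FileNotFoundError(f"required input {n!r} missing")
            out.append(Path(inputs[n]))
        return out

    state: dict = {}

    def _stage(name: str, fn) -> None:
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(outdir, manifest)
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {
            "status": "ok", "seconds": round(time.time() - t0, 3)
        }
        log.info("stage %s: done (%.1fs)", name, time.time() - t0)

    def _discover() -> None:
        cat_p, rf, ra = _require("catalog", "representatives_fasta",
                                 "representatives_annot")
        catalog = read_protein_fasta(cat_p)
        reps = read_representatives(rf, ra)
        calls, clusters = discover(
            catalog, reps,
            identity_threshold=config.identity_threshold,
            cluster_threshold=config.cluster_threshold,
            params=config.alignment,
            thresholds=config.class_thresholds,
            taxonomy_floor=config.taxonomy_floor,
            residue_check_mode=config.residue_check_mode,
        )
        state["catalog"], state["clusters"] = catalog, clusters
        calls_df = pd.DataFrame(
            [
                {
                    "candidate_id": c.candidate_id,
                    "best_rep": c.best_rep,
                    "best_identity": c.best_identity,
                    "residues_matched": sum(c.residue_matches),
                    "residue_matches": "".join(
                        "1" if b else "0" for b in c.residue_matches
                    ),
                    "accepted": int(c.accepted),
                    "reject_reason": c.reject_reason,
                }
                for c in calls
            ]
        )
        write_table(
            calls_df, outdir / "gus_calls.tsv",
            f"screen: identity > {config.identity_threshold} (strict) to the "
            f"best-scoring representative AND 7/7 conserved residues; {COORD_NOTE}",
        )
        cl_df = pd.DataFrame(
            [
                {
                    "cluster_id": cl.cluster_id,
                    "representative_id": cl.representative_id,
                    "member_ids": ";".join(cl.member_ids),
                    "n_members": len(cl.member_ids),
                    "gus_class": cl.gus_class,
                    "class_flag": cl.class_flag or None,
                    "taxonomy": cl.taxonomy,
                    "taxonomy_identity": cl.taxonomy_identity,
                }
                for cl in clusters
            ]
        )
        write_table(
            cl_df, outdir / "gusome_clusters.tsv",
            f"redundancy clustering at >= {config.cluster_threshold} identity "
            f"(identical columns / shorter length); {COORD_NOTE}",
        )
        if write_newick and clusters:
            (outdir / "clusters.nwk").write_text(
                clusters_to_newick(clusters, catalog, config.alignment) + "\n"
            )

    def _abundance() -> None:
        (counts_p,) = _require("counts")
        meta = read_metadata(_require("metadata")[0])
        sample_ids = [m.sample_id for m in meta]
        counts = read_table(counts_p, required=("gene_id", "length"),
                            numeric=["length", *sample_ids])
        table, scalars = ab.build_abundance_table(counts, sample_ids)
        state["gene_abundance"], state["abundance_scalars"] = table, scalars
        write_table(
            table, outdir / "gene_abundance.tsv",
            "relative_count = log10((count/total_in_sample)*(total_all/n_samples)+1); "
            f"normalized = relative + slope*(avg_len - len), slope="
            f"{scalars.get('bias_slope', 'per-sample'):.6g}, unit={config.length_unit}",
        )
        clusters = state.get("clusters") or _clusters_from_table(
            outdir / "gusome_clusters.tsv"
        )
        state.setdefault("clusters", clusters)
        cls_ab = ab.class_gene_abundance(table, clusters)
        state["class_abundance"] = cls_ab
        write_table(
            cls_ab.reset_index(), outdir / "class_abundance.tsv",
            "per-sample summed normalized gene abundance by GUS class",
        )
        tax_ab = ab.taxon_gene_abundance(table, clusters)
        state["taxon_abundance"] = tax_ab
        if not tax_ab.empty:
            write_table(
                tax_ab.reset_index(), outdir / "taxon_abundance.tsv",
                "per-sample summed normalized gene abundance by taxonomy label",
            )
        gene_mat = table.pivot_table(
            index="sample_id", columns="gene_id", values="normalized_abundance",
            fill_value=0.0,
        )
        shannon = {
            s: dv.shannon_index(np.clip(gene_mat.loc[s].to_numpy(), 0, None),
                                base=config.shannon_base)
            for s in gene_mat.index
            if gene_mat.loc[s].clip(lower=0).sum() > 0
        }
        write_table(
            pd.DataFrame(
                {"sample_id": list(shannon), "shannon": list(shannon.values())}
            ),
            outdir / "diversity.tsv",
            f"Shannon index, log base {config.shannon_base:g}, on normalized gene abundance",
        )
        beta = dv.distance_matrix(gene_mat.clip(lower=0))
        write_table(beta.reset_index(names="sample_id"), outdir / "beta.tsv",
                    "Bray-Curtis dissimilarity on normalized gene abundance")
        res = dv.pcoa(beta)
        pcoa_df = pd.DataFrame(
            res.coordinates,
            index=beta.index,
            columns=[f"PC{i + 1}" for i in range(res.coordinates.shape[1])],
        )
        write_table(
            pcoa_df.reset_index(names="sample_id"), outdir / "pcoa.tsv",
            "classical PCoA; proportion explained: "
            + ", ".join(f"{p:.4f}" for p in res.proportion_explained),
        )
        groups = [m.group for m in meta]
        perm = dv.permanova(beta.to_numpy(), groups,
                            n_perm=config.n_permutations, seed=config.seed)
        (outdir / "permanova.json").write_text(json.dumps(perm, indent=2) + "\n")

    def _proteomics() -> None:
        (pep_p,) = _require("peptides")
        peptides = read_table(pep_p, required=("sample_id", "peptide", "intensity"),
                              numeric=("intensity",))
        catalog = state.get("catalog") or read_protein_fasta(_require("catalog")[0])
        clusters = state.get("clusters") or _clusters_from_table(
            outdir / "gusome_clusters.tsv"
        )
        state.setdefault("catalog", catalog)
        state.setdefault("clusters", clusters)
        matches = pq.map_peptides(peptides, catalog, clusters)
        rows = pq.protein_intensity(matches, clusters)
        state["protein_intensity"] = rows
        write_table(rows, outdir / "protein_intensity.tsv",
                    "summed unique-peptide intensity per cluster per sample; log2 after summing")
        cls_int = pq.class_protein_abundance(rows)
        state["class_intensity"] = cls_int
        write_table(cls_int.reset_index(), outdir / "class_intensity.tsv",
                    "log2 of per-sample class-summed intensity; undetected = missing")
        by_id = {r.id: r for r in catalog}
        cov_rows = []
        for cl in clusters:
            rep_rec = by_id.get(cl.representative_id)
            if rep_rec is None:
                continue
            for sid, sub in peptides.groupby("sample_id"):
                peps = [
                    m.peptide for m in matches
                    if m.sample_id == sid and m.unique
                    and m.matched_clusters == (cl.cluster_id,)
                    and cl.representative_id in m.matched_proteins
                ]
                if peps:
                    cov_rows.append(
                        {
                            "cluster_id": cl.cluster_id,
                            "sample_id": sid,
                            "coverage": pq.sequence_coverage(rep_rec, set(peps)),
                        }
                    )
        write_table(pd.DataFrame(cov_rows,
                                 columns=["cluster_id", "sample_id", "coverage"]),
                    outdir / "coverage.tsv",
                    "fraction of cluster-representative residues covered by unique peptides")
        meta = read_metadata(_require("metadata")[0])
        tests = pq.group_tests(cls_int, {m.sample_id: m.group for m in meta})
        (outdir / "group_tests.json").write_text(
            tests.to_json(orient="records", indent=2) + "\n"
        )

    def _rates() -> None:
        (tc_p,) = _require("timecourses")
        tcs = read_table(tc_p, required=("sample_id", "replicate", "time_s", "mpag_nM"),
                         numeric=("time_s", "mpag_nM"))
        rates = kn.fit_rates(tcs)
        state["rates"] = rates
        write_table(
            pd.DataFrame(
                [
                    {
                        "sample_id": r.id,
                        "mean_rate_nM_per_s": r.mean_rate,
                        "sem": r.sem,
                        "log2_rate": r.log2_rate,
                        "replicate_rates": ";".join(f"{v:.6g}" for v in r.replicate_rates),
                        "r_squared": r.r_squared,
                        "flagged_rising": int(r.flagged_rising),
                    }
                    for r in rates
                ]
            ),
            outdir / "rates.tsv",
            "per-replicate |OLS slope| of MPAG nM vs time s; mean +/- SEM; log2 of mean",
        )

    def _associate() -> None:
        rates = state.get("rates")
        if rates is None:
            raise FileNotFoundError("rates stage must run before association")
        predictors: dict[str, pd.Series] = {}
        cls_int = state.get("class_intensity")
        if cls_int is not None and not cls_int.empty:
            rows = state["protein_intensity"]
            predictors["protein_total_GUS"] = pq.total_protein_abundance(rows)
            for cls in cls_int.columns:
                predictors[f"protein_class:{cls}"] = cls_int[cls]
        cls_ab = state.get("class_abundance")
        if cls_ab is not None:
            for cls in cls_ab.columns:
                predictors[f"gene_class:{cls}"] = cls_ab[cls]
        tax_ab = state.get("taxon_abundance")
        if tax_ab is not None and not tax_ab.empty:
            for tax in tax_ab.columns:
                predictors[f"taxon:{tax}"] = tax_ab[tax]
        assoc = kn.associate_rates(rates, predictors,
                                   reference=config.wald_reference)
        write_table(
            assoc, outdir / "associations.tsv",
            f"Wald slope test of log2 rate on each predictor; reference="
            f"{config.wald_reference}; no multiplicity adjustment",
        )

    stage_fns = {
        "discover": _discover,
        "abundance": _abundance,
        "proteomics": _proteomics,
        "rates": _rates,
        "associate": _associate,
    }
    for name in stages:
        if name not in stage_fns:
            raise ValueError(f"unknown stage {name!r}")
        _stage(name, stage_fns[name])
    manifest["complete"] = True
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n"
    )
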