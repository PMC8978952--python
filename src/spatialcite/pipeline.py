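"""End-to-end pipeline: simulate -> demux -> cluster -> transfer -> score.

Driven by a YAML run config; every stochastic stage derives its seed from
the single global seed, so a rerun with the same config reproduces
identical matrices and labels. A JSON manifest records parameters,
per-stage read/pixel tallies, stage timings, and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import chip as chip_mod
from . import io as pmio
from .cluster import cluster_pixels, differential_features
from .demux import TranscriptReference, demux_fastq, qc_per_pixel, qc_summary
from .integrate import SignatureDefinition, signature_score, transfer_labels
from .normalize import clr_normalize, log_normalize
from .simulate import (
    default_gene_list,
    emit_fastq,
    make_reference_atlas,
    make_reference_transcripts,
    make_tissue,
)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (exit code 2 in the CLI)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_CONFIG = {
    "seed": 0,
    "grid": [20, 20],
    "chip": None,  # path to chip YAML; None -> generated default at grid size
    "panel": None,  # path to panel TSV; None -> bundled small panel
    "simulate": {
        "n_domains": 3,
        "effect_size": 8.0,
        "error_rate": 0.005,
        "reads_per_umi_mean": 0.5,
        "n_genes": 60,
        "baseline_protein": 2.0,
        "baseline_rna": 1.0,
    },
    "demux": {"max_mismatch": 1, "umi_mode": "exact"},
    "cluster": {"n_dims": 30, "resolution": 0.5, "n_neighbors": 20},
    "transfer": {"n_cells_per_domain": 50, "n_dims": 30},
    "signature": {"name": "Tph", "features": ["LAG3", "PDCD1", "CXCR6"]},
    "plots": True,
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def validate_config(cfg: dict) -> None:
    for key in ("chip", "panel"):
        path = cfg.get(key)
        if path is not None and not os.path.exists(path):
            raise ConfigError(f"{key} file not found: {path}")
    if "outdir" not in cfg or not cfg["outdir"]:
        raise ConfigError("config must set 'outdir'")
    grid = cfg.get("grid", [0, 0])
    if len(grid) != 2 or min(grid) < 1:
        raise ConfigError(f"invalid grid {grid}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(cfg: dict, log=print) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    validate_config(cfg)
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    partial = os.path.join(outdir, ".partial")
    open(partial, "w").close()
    seed = int(cfg["seed"])
    manifest: dict = {"config": cfg, "stages": {}, "checksums": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log(f"[{name}] start")
            try:
                info = fn() or {}
            except (ConfigError, StageError):
                raise
            except Exception as exc:  # noqa: BLE001 - named stage failure
                raise StageError(name, exc) from exc
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
            log(f"[{name}] done in {info['seconds']}s")
            return info

        return wrap

    grid = tuple(cfg["grid"])
    if cfg["chip"]:
        design = chip_mod.load_chip_design(cfg["chip"])
    else:
        design = chip_mod.default_chip_design(n_rows=grid[0], n_cols=grid[1])
    if cfg["panel"]:
        panel = chip_mod.load_adt_panel(cfg["panel"])
    else:
        panel = chip_mod.small_panel()

    sim_cfg = cfg["simulate"]
    genes = default_gene_list(int(sim_cfg["n_genes"]))
    state: dict = {}

    @stage("simulate")
    def _simulate():
        truth = make_tissue(
            n_domains=int(sim_cfg["n_domains"]),
            grid=grid,
            effect_size=float(sim_cfg["effect_size"]),
            seed=seed,
            protein_features=panel.names,
            genes=genes,
            baseline_protein=float(sim_cfg["baseline_protein"]),
            baseline_rna=float(sim_cfg["baseline_rna"]),
            error_rate=float(sim_cfg["error_rate"]),
        )
        gene_seqs = make_reference_transcripts(genes, seed=seed)
        sim = emit_fastq(
            truth, design, panel, gene_seqs,
            os.path.join(outdir, "sim"),
            reads_per_umi_mean=float(sim_cfg["reads_per_umi_mean"]),
            seed=seed,
        )
        state["truth"], state["sim"], state["gene_seqs"] = truth, sim, gene_seqs
        return {"n_reads": sim.n_reads, "n_domains": truth.n_domains}

    @stage("demux")
    def _demux():
        sim = state["sim"]
        dm = cfg["demux"]
        ref = TranscriptReference(state["gene_seqs"])
        info = {}
        for modality, r1, r2 in (
            ("protein", sim.protein_r1, sim.protein_r2),
            ("rna", sim.rna_r1, sim.rna_r2),
        ):
            mat, summary, _ = demux_fastq(
                r1, r2, design, modality,
                panel=panel if modality == "protein" else None,
                reference=ref if modality == "rna" else None,
                max_mismatch=int(dm["max_mismatch"]),
                umi_mode=dm["umi_mode"],
            )
            pmio.write_matrix(mat, outdir, design)
            qc_per_pixel(mat).to_csv(
                os.path.join(outdir, modality, "qc_per_pixel.tsv"), sep="\t", index=False
            )
            state[f"matrix_{modality}"] = mat
            info[modality] = {**summary, "qc": qc_summary(mat)}
        return info

    @stage("cluster")
    def _cluster():
        cl = cfg["cluster"]
        info = {}
        for modality, normalizer in (("protein", clr_normalize), ("rna", log_normalize)):
            norm = normalizer(state[f"matrix_{modality}"])
            assign = cluster_pixels(
                norm,
                n_dims=int(cl["n_dims"]),
                resolution=float(cl["resolution"]),
                n_neighbors=int(cl["n_neighbors"]),
                seed=seed,
            )
            state[f"norm_{modality}"] = norm
            state[f"clusters_{modality}"] = assign
            pd.DataFrame(
                {"pixel": [p.label for p in norm.pixel_index], "cluster": assign.labels}
            ).to_csv(os.path.join(outdir, modality, "clusters.tsv"), sep="\t", index=False)
            de = differential_features(norm, assign)
            de.to_csv(os.path.join(outdir, modality, "markers.tsv"), sep="\t", index=False)
            truth_domains = np.asarray(
                [state["truth"].domain_of(p) for p in norm.pixel_index]
            )
            from sklearn.metrics import adjusted_rand_score

            ari = adjusted_rand_score(truth_domains, assign.labels)
            info[modality] = {"n_clusters": assign.n_clusters, "ari_vs_truth": round(ari, 4)}
            if cfg.get("plots"):
                from .plot import spatial_map

                spatial_map(
                    norm.parent, assign.labels,
                    os.path.join(outdir, modality, "cluster_map.png"),
                    title=f"{modality} clusters", categorical=True,
                )
        return info

    @stage("transfer")
    def _transfer():
        tr = cfg["transfer"]
        ref = make_reference_atlas(state["truth"], int(tr["n_cells_per_domain"]), seed + 1)
        table = transfer_labels(
            state["norm_rna"], ref,
            n_dims=int(tr["n_dims"]),
            clusters=state["clusters_rna"],
        )
        table.to_csv(os.path.join(outdir, "rna", "cell_types.tsv"), sep="\t", index=False)
        truth_types = np.asarray(
            [f"type{state['truth'].domain_of(p)}" for p in state["norm_rna"].pixel_index]
        )
        acc = float((table["predicted_type"].to_numpy() == truth_types).mean())
        acc_sm = float((table["smoothed_type"].to_numpy() == truth_types).mean())
        return {"accuracy": round(acc, 4), "accuracy_smoothed": round(acc_sm, 4)}

    @stage("score")
    def _score():
        sig_cfg = cfg["signature"]
        sig = SignatureDefinition(sig_cfg["name"], list(sig_cfg["features"]))
        scores = signature_score(state["norm_rna"], sig)
        pd.DataFrame(
            {"pixel": [p.label for p in state["norm_rna"].pixel_index], "score": scores}
        ).to_csv(os.path.join(outdir, "rna", f"{sig.name}_score.tsv"), sep="\t", index=False)
        if cfg.get("plots"):
            from .plot import spatial_map

            spatial_map(
                state["norm_rna"].parent, scores,
                os.path.join(outdir, "rna", f"{sig.name}_score_map.png"),
                title=f"{sig.name} signature score",
            )
        return {"signature": sig.name, "score_mean": float(np.mean(scores))}

    for modality in ("protein", "rna"):
        mtx = os.path.join(outdir, modality, "matrix.mtx")
        if os.path.exists(mtx):
            manifest["checksums"][f"{modality}/matrix.mtx"] = _sha256(mtx)
    manifest["read_conservation"] = all(
        sum(s["status_counts"].values()) == s["n_reads"]
        for s in (manifest["stages"]["demux"]["protein"], manifest["stages"]["demux"]["rna"])
    )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    os.remove(partial)
    return manifest
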