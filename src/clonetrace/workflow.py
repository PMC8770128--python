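"""End-to-end pipeline stages behind the command-line interface.

Each stage reads its inputs from ``config.inputs``, runs the corresponding
library module, writes CSV artifacts carrying a metadata block (parameters,
seed, package version) and logs the record funnel (records in, surviving
each filter, cells called, clones formed). All stages are deterministic
given the seeds in the config.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .collision import CollisionConfig, simulate_collisions
from .config import RunConfig
from .coupling import StateAnnotation, coupling_zscores, lineage_dendrogram
from .io import read_matrix, read_reads, read_table, write_reads_fastq, write_reads_tsv, write_table
from .mapping import map_embryonic_cells, mapping_fractions
from .sticr import CloneTable, FragmentReference, ReadLayout, SticrParams, call_sticr_clones
from .synthetic import (
    gen_barcode_library,
    gen_clonal_population,
    gen_expression_pair,
    gen_reads,
)
from .trackerseq import TrackerParams, call_clones_jaccard, filter_integrations

log = logging.getLogger("clonetrace")


def _meta(config: RunConfig, **extra) -> dict:
    return {"version": __version__, "seed": config.seed, **extra}


def _out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: RunConfig) -> dict:
    """Generate a synthetic dataset (reads + ground truth + references)."""
    out = _out(config)
    mode = config.inputs.get("mode", "sticr")
    n_clones = int(config.inputs.get("n_clones", 100))
    pool_sizes = tuple(config.inputs.get("pool_sizes", (50, 50, 50)))
    library = gen_barcode_library(pool_sizes, seed=config.seed) if mode == "sticr" else None
    pop = gen_clonal_population(
        n_clones=n_clones,
        states=config.inputs.get("states", ["s1", "s2", "s3", "s4"]),
        mode=mode,
        seed=config.seed,
        pool_sizes=pool_sizes,
    )
    reads = gen_reads(pop, library, seed=config.seed + 1)
    artifacts = {}
    write_reads_tsv(reads, out / "reads.tsv")
    write_reads_fastq(reads, out / "reads.fastq")
    write_table(pop.truth_frame(), out / "truth.csv", _meta(config, mode=mode))
    barcode_map = pd.DataFrame(
        {"cell": list(reads.cell_barcode_of), "cell_barcode": list(reads.cell_barcode_of.values())}
    )
    write_table(barcode_map, out / "cell_barcodes.csv", _meta(config))
    if library is not None:
        for i, pool in enumerate(library.pools):
            (out / f"pool{i + 1}.txt").write_text("\n".join(pool) + "\n")
        (out / "viral_indices.txt").write_text(library.viral_index + "\n")
    artifacts.update(
        reads_tsv=out / "reads.tsv",
        reads_fastq=out / "reads.fastq",
        truth=out / "truth.csv",
    )
    log.info("simulate: %d cells, %d clones, %d read records", len(pop.cells), n_clones, len(reads.records))
    return artifacts


def _load_reference(config: RunConfig) -> FragmentReference:
    pools_dir = Path(config.inputs["pools_dir"])
    pools = []
    for i in range(1, 4):
        f = pools_dir / f"pool{i}.txt"
        if not f.exists():
            raise FileNotFoundError(f"missing fragment pool file: {f}")
        pools.append(tuple(f.read_text().split()))
    vi = (pools_dir / "viral_indices.txt").read_text().split()
    return FragmentReference(pools=tuple(pools), viral_indices=tuple(vi))


def run_sticr(config: RunConfig) -> dict:
    """STICR clone calling from a reads file plus fragment pools."""
    out = _out(config)
    reads_path = Path(config.inputs["reads"])
    if not reads_path.exists():
        raise FileNotFoundError(f"missing reads file: {reads_path}")
    fmt = config.inputs.get("reads_format", "tsv")
    reads = read_reads(reads_path, format=fmt)
    reference = _load_reference(config)
    params = SticrParams(**config.sticr)
    layout = ReadLayout(fragment_length=len(reference.pools[0][0]),
                        viral_index_length=len(reference.viral_indices[0]))
    calls, table, funnel = call_sticr_clones(
        reads.records, reference, params,
        layout=layout,
        dataset=config.inputs.get("dataset", "ds0"),
        tier_policy=config.tier_policy,
    )
    for k, v in funnel.items():
        log.info("sticr funnel: %s=%s", k, v)
    meta = _meta(config, **{f"param_{k}": v for k, v in vars(params).items()}, **funnel)
    write_table(calls, out / "barcode_calls.csv", meta)
    write_table(table.to_frame(), out / "clones.csv", meta)
    return {"calls": out / "barcode_calls.csv", "clones": out / "clones.csv", "funnel": funnel}


def run_trackerseq(config: RunConfig) -> dict:
    """TrackerSeq integration filtering and Jaccard clone calling."""
    out = _out(config)
    rec_path = Path(config.inputs["records"])
    if not rec_path.exists():
        raise FileNotFoundError(f"missing records file: {rec_path}")
    records = pd.read_csv(rec_path, sep=None, engine="python")
    params = TrackerParams(cut_height=config.cut_height, **config.tracker)
    matrix = filter_integrations(records, params)
    for k, v in matrix.diagnostics.items():
        log.info("trackerseq funnel: %s=%s", k, v)
    meta = _meta(
        config,
        cut_scale="jaccard_distance",
        **{f"param_{k}": v for k, v in vars(params).items()},
        **matrix.diagnostics,
    )
    mat_df = matrix.to_frame().reset_index(names="cell")
    write_table(mat_df, out / "integration_matrix.csv", meta)
    if len(matrix.cells) == 0:
        log.warning("trackerseq: empty matrix after filtering; no clones called")
        return {"matrix": out / "integration_matrix.csv", "clones": None}
    table = call_clones_jaccard(matrix, params, dataset=config.inputs.get("dataset", "ds0"))
    write_table(table.to_frame(), out / "clones.csv", meta)
    return {"matrix": out / "integration_matrix.csv", "clones": out / "clones.csv"}


def run_coupling(config: RunConfig) -> dict:
    """Permutation lineage-coupling z-scores and correlations."""
    out = _out(config)
    clones_df, _ = read_table(Path(config.inputs["clones"]))
    ann_df, _ = read_table(Path(config.inputs["annotation"]))
    table = CloneTable.from_frame(clones_df)
    ann = StateAnnotation.from_frame(ann_df)
    if len(ann.states) < 2:
        raise ValueError("coupling requires >= 2 states")
    result = coupling_zscores(table, ann, n_perm=config.n_perm, seed=config.seed)
    meta = _meta(config, n_perm=config.n_perm, n_states=len(ann.states), n_clones=len(table.clones))
    artifacts = {}
    for name, frame in [
        ("observed", result.observed),
        ("null_mean", result.null_mean),
        ("null_sd", result.null_sd),
        ("zscores", result.z),
        ("correlations", result.corr),
    ]:
        path = out / f"coupling_{name}.csv"
        write_table(frame.reset_index(names="state"), path, meta)
        artifacts[name] = path
    _, groups = lineage_dendrogram(result.corr, n_groups=min(4, len(ann.states)))
    write_table(groups.rename_axis("state").reset_index(), out / "clonal_groups.csv", meta)
    artifacts["groups"] = out / "clonal_groups.csv"
    log.info("coupling: %d states, %d clones, %d permutations", len(ann.states), len(table.clones), config.n_perm)
    return artifacts


def run_mapping(config: RunConfig) -> dict:
    """Correlation-based mapping of embryonic cells to postnatal clusters."""
    out = _out(config)
    emb = read_matrix(Path(config.inputs["embryonic"]), config.inputs.get("matrix_format", "csv"))
    post = read_matrix(Path(config.inputs["postnatal"]), config.inputs.get("matrix_format", "csv"))
    post_labels_df, _ = read_table(Path(config.inputs["postnatal_labels"]))
    post_labels = pd.Series(
        post_labels_df["cluster"].values, index=post_labels_df["cell"].values
    )
    genes_path = config.inputs.get("genes")
    genes = (
        Path(genes_path).read_text().split() if genes_path else [g for g in emb.columns if g in post.columns]
    )
    result = map_embryonic_cells(
        emb, post, post_labels, genes,
        n_perm=config.mapping_n_perm,
        fdr_threshold=config.fdr_threshold,
        seed=config.seed,
        scheme=config.permutation_scheme,
    )
    meta = _meta(config, **result.attrs["params"], n_genes=len(genes))
    write_table(result.reset_index(names="cell"), out / "mapping.csv", meta)
    artifacts = {"mapping": out / "mapping.csv"}
    emb_labels_path = config.inputs.get("embryonic_labels")
    if emb_labels_path:
        emb_labels_df, _ = read_table(Path(emb_labels_path))
        emb_labels = pd.Series(emb_labels_df["cluster"].values, index=emb_labels_df["cell"].values)
        frac = mapping_fractions(result, emb_labels)
        write_table(frac.reset_index(names="embryonic_cluster"), out / "mapping_fractions.csv", meta)
        artifacts["fractions"] = out / "mapping_fractions.csv"
    log.info("mapping: %d cells, %d mapped", len(result), int(result["mapped"].sum()))
    return artifacts


def run_collide(config: RunConfig) -> dict:
    """Barcode-collision curve over labelled-population sizes."""
    out = _out(config)
    D = int(config.inputs.get("library_size", 65_000_000))
    sigma = config.inputs.get("abundance_sigma")
    abundances = None
    if sigma is not None:
        rng = np.random.default_rng(config.seed)
        w = rng.lognormal(0.0, float(sigma), size=D)
        abundances = w / w.sum()
    cfg = CollisionConfig(
        library_size=D,
        abundances=abundances,
        population_sizes=tuple(config.inputs.get("population_sizes", (10, 100, 1000, 10000, 100000, 1000000))),
        n_reps=int(config.inputs.get("n_reps", 20000)),
        seed=config.seed,
    )
    curve = simulate_collisions(cfg)
    write_table(curve, out / "collision_curve.csv", _meta(config, library_size=D, abundance_sigma=sigma))
    return {"curve": out / "collision_curve.csv"}


_COMMANDS = {
    "simulate": run_simulate,
    "sticr": run_sticr,
    "trackerseq": run_trackerseq,
    "coupling": run_coupling,
    "mapping": run_mapping,
    "collide": run_collide,
}


def run_pipeline(config: RunConfig, command: str) -> dict:
    """Dispatch a pipeline stage; partial outputs are removed on failure."""
    if command not in _COMMANDS:
        raise ValueError(f"unknown command: {command!r}")
    out = Path(config.out_dir)
    before = set(out.glob("*")) if out.exists() else set()
    try:
        return _COMMANDS[command](config)
    except Exception:
        if out.exists():
            for f in set(out.glob("*")) - before:
                if f.is_file():
                    f.unlink()
        raise
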