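"""End-to-end synthetic pipeline runner with a reproducibility manifest.

``run_pipeline`` executes the requested stages in dependency order on fully
synthetic data: simulate paired tight/spread colony images (plus a gene
universe and an smFISH stack), quantify them into cell tables, build the
dose-response curve, compare packing between conditions, count transcripts,
and run the overlap bootstrap.  Every stage derives its seed from the single
config seed, and the manifest records the SHA-256 of every output so that an
identical config reproduces identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, singlecell, smfish, spatial, synth
from .enrichment import EnrichmentConfig, assign_peaks_to_genes, bootstrap_overlap
from .io import RunConfig, read_table, sha256_file, write_bed, write_image, write_table

__all__ = ["run_pipeline"]

_DEPS = {
    "simulate": (),
    "quantify": ("simulate",),
    "doseresponse": ("quantify",),
    "spatial": ("quantify",),
    "smfish": ("simulate",),
    "enrich": ("simulate",),
}

_CONDITIONS = ("tight", "spread")


def _check_dependencies(stages: list[str]) -> None:
    done: set[str] = set()
    for stage in stages:
        missing = [d for d in _DEPS[stage] if d not in done]
        if missing:
            raise ValueError(
                f"stage {stage!r} requires upstream output of {missing[0]!r}, "
                "which is not scheduled before it"
            )
        done.add(stage)


def _to_uint16(image: np.ndarray) -> np.ndarray:
    return np.clip(np.round(image), 0, 65535).astype(np.uint16)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; return (and write) the output manifest."""
    from . import __version__

    _check_dependencies(config.stages)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "params": {s: config.params.get(s, {}) for s in config.stages},
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    def record(stage: str, name: str, path: Path) -> None:
        manifest["stages"].setdefault(stage, {})[name] = sha256_file(path)
        outputs[f"{stage}/{name}"] = path

    for stage in config.stages:
        params = config.params.get(stage, {})
        if stage == "simulate":
            _stage_simulate(config, params, outdir, record)
        elif stage == "quantify":
            _stage_quantify(config, params, outdir, record)
        elif stage == "doseresponse":
            _stage_doseresponse(config, params, outdir, record)
        elif stage == "spatial":
            _stage_spatial(outdir, record)
        elif stage == "smfish":
            _stage_smfish(params, outdir, record)
        elif stage == "enrich":
            _stage_enrich(config, params, outdir, record)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(config, params, outdir, record):
    n_colonies = int(params.get("n_colonies", 3))
    nuclei = tuple(params.get("nuclei_per_colony", (14, 0)))
    shape = tuple(params.get("image_shape_px", (512, 512)))
    for i, mode in enumerate(_CONDITIONS):
        colony = synth.ColonyParams(
            n_colonies=n_colonies,
            nuclei_per_colony=nuclei,
            packing_mode=mode,
            image_shape_px=shape,
            seed=config.seed + i,
        )
        expr = synth.ExpressionParams(seed=config.seed + 10 + i)
        stack, truth = synth.generate_colony_image(colony, expr)
        for name, img in stack.channels.items():
            path = outdir / f"sim_{mode}_{name}.tif"
            write_image(path, _to_uint16(img))
            record("simulate", path.name, path)
        tpath = outdir / f"sim_{mode}_truth.tsv"
        write_table(truth, tpath)
        record("simulate", tpath.name, tpath)
        labels = synth.ground_truth_labels(truth, shape)
        lpath = outdir / f"sim_{mode}_labels.tif"
        write_image(lpath, labels.astype(np.uint16))
        record("simulate", lpath.name, lpath)

    genes, peaks = synth.generate_gene_universe(
        n_genes=int(params.get("n_genes", 1000)),
        peak_fraction=float(params.get("peak_fraction", 0.137)),
        genome_length=int(params.get("genome_length", 40_000_000)),
        seed=config.seed + 20,
    )
    gpath, ppath = outdir / "sim_genes.tsv", outdir / "sim_peaks.bed"
    write_table(genes, gpath)
    write_bed(peaks, ppath)
    record("simulate", gpath.name, gpath)
    record("simulate", ppath.name, ppath)

    labels = synth.ground_truth_labels(
        read_table(outdir / "sim_tight_truth.tsv"), shape
    )
    spot_stack, spot_truth = synth.generate_spot_stack(
        labels, synth.SpotParams(seed=config.seed + 30)
    )
    spath = outdir / "sim_fish_stack.tif"
    write_image(spath, _to_uint16(spot_stack))
    record("simulate", spath.name, spath)
    stpath = outdir / "sim_fish_truth.tsv"
    write_table(spot_truth, stpath)
    record("simulate", stpath.name, stpath)


def _stage_quantify(config, params, outdir, record):
    import tifffile

    backgrounds = {}
    for mode in _CONDITIONS:
        channels = {}
        for name in ("DAPI", "mCherry", "NANOG"):
            channels[name] = tifffile.imread(outdir / f"sim_{mode}_{name}.tif").astype(float)
        stack = imaging.ImageStack(channels=channels)
        bg = {}
        for name, img in channels.items():
            # fold normalisation divides the raw nuclear mean by this estimate
            _, est = imaging.subtract_background(img, method="percentile")
            bg[name] = float(est)
        labels = imaging.segment_nuclei(stack["DAPI"])
        cells = imaging.measure_nuclei(labels, stack)
        path = outdir / f"cells_{mode}.tsv"
        write_table(cells, path)
        record("quantify", path.name, path)
        backgrounds[mode] = bg
    bpath = outdir / "backgrounds.json"
    with open(bpath, "w") as fh:
        json.dump(backgrounds, fh, indent=2, sort_keys=True)
    record("quantify", bpath.name, bpath)


def _stage_doseresponse(config, params, outdir, record):
    with open(outdir / "backgrounds.json") as fh:
        backgrounds = json.load(fh)
    tables = []
    for mode in _CONDITIONS:
        cells = read_table(outdir / f"cells_{mode}.tsv")
        cells["fold_driver"] = singlecell.fold_over_background(
            cells, "mCherry", backgrounds[mode]["mCherry"]
        )
        cells["fold_response"] = singlecell.fold_over_background(
            cells, "NANOG", backgrounds[mode]["NANOG"]
        )
        tables.append(cells)
    cells = pd.concat(tables, ignore_index=True)
    on, _ = singlecell.classify_on_off(
        cells["fold_response"].to_numpy(), method="gmm2_log", seed=config.seed
    )
    curve = singlecell.dose_response(cells["fold_driver"].to_numpy(), on)
    path = outdir / "dose_response.tsv"
    write_table(curve, path)
    record("doseresponse", path.name, path)


def _stage_spatial(outdir, record):
    dists = {}
    for mode in _CONDITIONS:
        cells = read_table(outdir / f"cells_{mode}.tsv")
        pts = spatial.points_from_cells(cells)
        dists[mode] = spatial.nearest_neighbor_distances(pts)
        dtab = pd.DataFrame({"label": cells["label"], "nn_distance": dists[mode]})
        path = outdir / f"nn_{mode}.tsv"
        write_table(dtab, path)
        record("spatial", path.name, path)
    summary = spatial.compare_nn_distributions(dists["tight"], dists["spread"])
    path = outdir / "nn_comparison.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    record("spatial", path.name, path)


def _stage_smfish(params, outdir, record):
    import tifffile

    stack = tifffile.imread(outdir / "sim_fish_stack.tif").astype(float)
    labels = tifffile.imread(outdir / "sim_tight_labels.tif").astype(np.int32)
    spots, counts = smfish.count_transcripts(
        stack, labels, sigma_px=float(params.get("sigma_px", 1.5))
    )
    spath, cpath = outdir / "fish_spots.tsv", outdir / "fish_counts.tsv"
    write_table(spots, spath)
    write_table(counts, cpath)
    record("smfish", spath.name, spath)
    record("smfish", cpath.name, cpath)


def _stage_enrich(config, params, outdir, record):
    genes = read_table(outdir / "sim_genes.tsv")
    peaks = pd.read_csv(
        outdir / "sim_peaks.bed", sep="\t", names=["chrom", "start", "end"]
    )
    universe = assign_peaks_to_genes(peaks, genes)
    # demo DE list with a planted peak excess over the ~K/N chance rate
    rng = np.random.default_rng(config.seed + 40)
    n_draw = int(params.get("n_draw", 292))
    n_hit = int(params.get("n_de_with_peak", 114))
    flagged = universe.loc[universe["has_peak"], "gene_id"].to_numpy()
    unflagged = universe.loc[~universe["has_peak"], "gene_id"].to_numpy()
    de = np.concatenate(
        [
            rng.choice(flagged, size=min(n_hit, len(flagged)), replace=False),
            rng.choice(unflagged, size=n_draw - min(n_hit, len(flagged)), replace=False),
        ]
    )
    result = bootstrap_overlap(
        list(de),
        universe,
        EnrichmentConfig(
            n_draw=n_draw,
            n_iter=int(params.get("n_iter", 10_000)),
            seed=config.seed + 41,
        ),
    )
    path = outdir / "enrichment.json"
    with open(path, "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
    record("enrich", path.name, path)
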