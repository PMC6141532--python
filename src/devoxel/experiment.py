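"""Experiment orchestration: run trials over a seed list and write a
self-describing artifact directory (history CSVs, champion genome archives,
lineage records, and a manifest with content hashes)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

from . import __version__
from .analysis import trace_lineage
from .config import ExperimentConfig, substream
from .evolution import run_trial
from .genome import Genome

__all__ = ["run_experiment"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh)


def run_experiment(
    cfg: ExperimentConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
    resume: bool = False,
    progress: bool = False,
) -> Path:
    """Run every seed of the experiment and write the artifact directory.

    Refuses to write into a non-empty directory unless ``overwrite`` or
    ``resume`` is given; with ``resume``, seeds whose outputs are already in
    the manifest are skipped. Returns the output directory path.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    manifest_path = out / "manifest.json"
    completed: set[int] = set()
    if out.exists() and any(out.iterdir()):
        if resume and manifest_path.exists():
            with open(manifest_path) as fh:
                completed = set(json.load(fh).get("seeds_completed", []))
        elif not overwrite:
            raise FileExistsError(
                f"output directory {out} is not empty; pass overwrite=True or resume=True"
            )
    out.mkdir(parents=True, exist_ok=True)

    evo_cfg = cfg.evo_config()
    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()

    for seed in cfg.seeds:
        if seed in completed:
            continue
        rng = substream(seed, 0)  # trial stream; analysis stages use other keys
        log, champion = run_trial(evo_cfg, seed=rng, progress=progress)
        log.to_csv(out / f"history_seed{seed}.csv")
        _write_json(
            out / f"champion_seed{seed}.json",
            {
                "seed": seed,
                "uid": int(champion.uid),
                "age": int(champion.age),
                "fitness": champion.fitness,
                "genome": champion.genome.to_dict(),
            },
        )
        lineage = trace_lineage(log, champion)
        _write_json(
            out / f"lineage_seed{seed}.json",
            {
                "seed": seed,
                "ancestors": [
                    {
                        "uid": int(u),
                        "generation": int(g),
                        "fitness": float(f),
                        "w_morph": float(wl),
                        "w_ctrl": float(wc),
                        "genome": genome.to_dict(),
                    }
                    for u, g, f, wl, wc, genome in zip(
                        lineage.uids,
                        lineage.generations,
                        lineage.fitness,
                        lineage.w_morph,
                        lineage.w_ctrl,
                        lineage.genomes,
                    )
                ],
            },
        )
        completed.add(seed)

        files = {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json"
        }
        _write_json(
            manifest_path,
            {
                "schema": "devoxel-manifest-v1",
                "package_version": __version__,
                "config": cfg_dict,
                "config_sha256": cfg_hash,
                "seeds_completed": sorted(completed),
                "files": files,
            },
        )
    return out
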