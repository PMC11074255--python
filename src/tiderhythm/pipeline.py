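"""End-to-end pipeline: simulate -> filter -> rhythm -> S_DR / dominance -> report.

One YAML config drives the whole run.  Every population x group condition is
either simulated (an expression-simulator config block) or loaded from a TSV
path; all randomness derives from the single top-level seed through
per-condition ``SeedSequence`` children, so identical config + seed gives
byte-identical artifact files.  Float tables are written with 12 significant
digits (see :mod:`tiderhythm.io`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .filters import filter_expression
from .io import load_yaml_config, read_expression_matrix, \
    write_expression_matrix, FLOAT_FMT
from .rain import CIRCADIAN_WINDOW, CIRCATIDAL_WINDOW, detect_rhythms, \
    rhythm_class_transitions
from .sdr import compute_sdr_table, dominance_log_ratio, gaussian_null_pvalues
from .simulate import ExpressionSimConfig, generate_expression_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

GROUPS = ("control", "treatment")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``populations`` maps population name -> {"control": block, "treatment":
    block}, where each block is either expression-simulator parameters or
    {"path": <matrix TSV>}.
    """

    seed: int
    populations: dict
    outdir: str = "tiderhythm_out"
    dt_hours: float = 3.1
    alpha: float = 0.01
    min_mean_tpm: float = 1.0
    min_peak_trough: float = 1.3
    fdr_threshold: float = 0.05
    sdr_include: str = "either"

    def __post_init__(self):
        if not self.populations:
            raise ValueError("config must define at least one population")
        for pop, groups in self.populations.items():
            missing = [g for g in GROUPS if g not in groups]
            if missing:
                raise ValueError(f"population {pop!r} lacks group(s): {missing}")
        for name, lo, hi in (("alpha", 0, 1), ("fdr_threshold", 0, 1)):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi})")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**load_yaml_config(path))

    def analysis_fields(self) -> dict:
        d = asdict(self)
        d.pop("outdir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_fields(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _condition_matrix(cfg: PipelineConfig, pop: str, group: str,
                      seed: int, outdir: Path):
    block = dict(cfg.populations[pop][group])
    if "path" in block:
        matrix = read_expression_matrix(block["path"], population=pop, group=group)
        truth = None
    else:
        block.setdefault("dt_hours", cfg.dt_hours)
        block.setdefault("seed", seed)
        sim = ExpressionSimConfig(**block)
        matrix, truth = generate_expression_dataset(sim, population=pop, group=group)
    write_expression_matrix(matrix, outdir / f"{pop}_{group}_matrix.tsv")
    if truth is not None:
        truth.to_csv(outdir / f"{pop}_{group}_truth.tsv", sep="\t",
                     index=False, float_format=FLOAT_FMT)
    return matrix


def _write_results(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for each population x group; return the run report.

    Artifacts land in ``config.outdir``: per condition the (simulated)
    matrix, truth table, filtered matrix and rhythm results; per population
    the S_DR table with Gaussian-null p-values and BH FDR, dominance tables
    and the circadian->circatidal transition gene list; plus ``report.json``
    and a log file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("tiderhythm")
    root.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))
    root.setLevel(logging.INFO)

    t_start = time.time()
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "thresholds": {
            "alpha": config.alpha,
            "min_mean_tpm": config.min_mean_tpm,
            "min_peak_trough": config.min_peak_trough,
            "fdr_threshold": config.fdr_threshold,
        },
        "populations": {},
        "timestamps": {"start": t_start},
    }
    windows = (CIRCATIDAL_WINDOW, CIRCADIAN_WINDOW)

    pops = sorted(config.populations)
    seeds = _condition_seeds(config.seed, pops)
    try:
        for pop in pops:
            pop_report: dict = {}
            results = {}
            matrices = {}
            for group in GROUPS:
                stage = f"{pop}/{group}"
                t0 = time.time()
                try:
                    matrix = _condition_matrix(config, pop, group,
                                               seeds[(pop, group)], outdir)
                    filtered, freport = filter_expression(
                        matrix, config.min_mean_tpm, config.min_peak_trough)
                    write_expression_matrix(
                        filtered, outdir / f"{pop}_{group}_filtered.tsv")
                    res, sets = detect_rhythms(filtered, windows=windows,
                                               alpha=config.alpha)
                    _write_results(res, outdir / f"{pop}_{group}_rhythm.tsv")
                except Exception as err:
                    raise RuntimeError(
                        f"stage {stage!r} failed; partial outputs in {outdir}"
                    ) from err
                results[group] = res
                matrices[group] = filtered
                pop_report[group] = {
                    "filter": freport.to_dict(),
                    "n_significant": {w: len(sets[w]) for w in sets},
                }
                logger.info("%s: %d genes in, %d retained, "
                            "circatidal %d / circadian %d significant (%.1f s)",
                            stage, freport.n_input, freport.n_retained,
                            len(sets["circatidal"]), len(sets["circadian"]),
                            time.time() - t0)

            sdr = compute_sdr_table(results["control"], results["treatment"],
                                    matrices["control"], matrices["treatment"],
                                    include=config.sdr_include)
            sdr = gaussian_null_pvalues(sdr)
            _write_results(sdr, outdir / f"{pop}_sdr.tsv")
            n_hits = int((sdr["fdr"] < config.fdr_threshold).sum())
            dom = {}
            for group in GROUPS:
                table, summary = dominance_log_ratio(results[group], results[group])
                _write_results(table, outdir / f"{pop}_{group}_dominance.tsv")
                dom[group] = summary
            common = (set(results["control"]["gene_id"])
                      & set(results["treatment"]["gene_id"]))
            trans = rhythm_class_transitions(
                _restrict(results["control"], common),
                _restrict(results["treatment"], common),
                alpha=config.alpha)
            pd.Series(sorted(trans), name="gene_id").to_csv(
                outdir / f"{pop}_transitions.tsv", sep="\t", index=False)
            pop_report["sdr"] = {"n_included": int(len(sdr)),
                                 "n_hits_fdr": n_hits}
            pop_report["dominance"] = dom
            pop_report["n_circadian_to_circatidal"] = len(trans)
            report["populations"][pop] = pop_report
            logger.info("%s: %d S_DR genes, %d FDR hits, dominance "
                        "control %.3f / treatment %.3f", pop, len(sdr), n_hits,
                        dom["control"]["mean"], dom["treatment"]["mean"])
    finally:
        root.removeHandler(handler)
        handler.close()

    report["timestamps"]["end"] = time.time()
    report["timestamps"]["elapsed_s"] = report["timestamps"]["end"] - t_start
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _restrict(results: pd.DataFrame, genes: set) -> pd.DataFrame:
    return results[results["gene_id"].isin(genes)]


def _condition_seeds(seed: int, pops) -> dict:
    """Stable per-condition integer seeds derived from the master seed."""
    keys = [(pop, group) for pop in pops for group in GROUPS]
    children = np.random.SeedSequence(seed).spawn(len(keys))
    return {k: int(c.generate_state(1)[0] & 0x7FFFFFFF)
            for k, c in zip(keys, children)}
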