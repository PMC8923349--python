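"""End-to-end orchestration: one config in, a bundle of tables + manifest out.

Stages, per abundance measure: temperature-bin summaries, D-statistic
permutation test, phylogenetic-signal estimate, whole-range + category
PGLS, segmental sliding-window PGLS, and the penalized-spline smooth with
its derivative-based transition localization.  Every stage writes one TSV
or JSON artifact; a manifest records status, sizes and seeds so runs are
auditable and byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_data import TraitTable, match_tree_table, read_trait_table, read_tree
from .phylo import estimate_lambda_signal, pgls_fit, phylo_covariance
from .smooth import derivative, fit_smooth
from .transition import bin_summaries, d_curve, d_max, permutation_test
from .windows import CategorySpec, category_pgls, segmental_pgls

logger = logging.getLogger(__name__)

#: fixed float formatting so repeated runs are byte-identical
FLOAT_FMT = "%.6g"

DEFAULT_CATEGORIES = [
    CategorySpec("low", 4, 34),
    CategorySpec("moderate", 35, 49),
    CategorySpec("high", 50, 85),
]


@dataclass
class RunConfig:
    trait_table: str
    tree: str
    out_dir: str
    measures: list[str] | None = None
    column_map: dict | None = None
    bin_width: int = 5
    d_window: tuple[int, int] = (20, 64)
    n_perm: int = 1000
    seed: int = 0
    window_size: int = 200
    window_stride: int = 1
    categories: list[CategorySpec] = field(default_factory=lambda: list(DEFAULT_CATEGORIES))
    basis_dim: int = 10
    p_variant: str = "strict"
    run_scan: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "categories" in raw:
            raw["categories"] = [CategorySpec(**c) for c in raw["categories"]]
        if "d_window" in raw:
            raw["d_window"] = tuple(raw["d_window"])
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage; stage failures are recorded, independent stages continue.

    Returns the manifest (also written to ``out_dir/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {"trait_table": str(config.trait_table), "tree": str(config.tree)},
    }

    table = read_trait_table(config.trait_table, config.column_map)
    tree = read_tree(config.tree)
    tree, table, drop_report = match_tree_table(tree, table)
    cov = phylo_covariance(tree)
    manifest["n_species"] = len(table)
    manifest["dropped"] = {k: len(v) for k, v in drop_report.items()}
    measures = config.measures or table.measures

    def stage(name: str, fn):
        t0 = time.time()
        try:
            fn()
            manifest["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 3)}
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
        logger.info("stage %-28s %s", name, manifest["stages"][name]["status"])

    topt = table.column("topt_c")

    def _bins(m):
        rows = [vars(b) for b in bin_summaries(topt, table.column(m), config.bin_width)]
        _write_tsv(pd.DataFrame(rows), out / f"bins_{m}.tsv")

    def _dtest(m):
        if config.n_perm == 0:
            manifest["stages"][f"dtest_{m}"] = {"status": "skipped", "reason": "n_perm=0"}
            return
        lo, hi = config.d_window
        curve = d_curve(topt, table.column(m))
        _write_tsv(
            pd.DataFrame(
                {
                    "i": curve.i_values,
                    "d": curve.d_values,
                    "n_lower": curve.n_lower,
                    "n_upper": curve.n_upper,
                }
            ),
            out / f"dcurve_{m}.tsv",
        )
        res = permutation_test(
            topt, table.column(m), n_perm=config.n_perm, lo=lo, hi=hi,
            seed=config.seed, p_variant=config.p_variant,
        )
        _write_tsv(pd.DataFrame({"null_dmax": res.null_dmax}), out / f"dnull_{m}.tsv")
        _write_json(
            {
                "d_max": res.observed.d_max,
                "argmax": res.observed.argmax_i,
                "p": res.p_value,
                "n_perm": res.n_perm,
                "seed": res.seed,
                "window": list(res.observed.window),
            },
            out / f"dtest_{m}.json",
        )

    def _signal():
        rows = []
        for name in measures + ["topt_c"]:
            est = estimate_lambda_signal(table.column(name), cov)
            rows.append(
                {
                    "trait": name,
                    "lambda_hat": est.lambda_hat,
                    "p": est.p_value,
                    "loglik": est.loglik_at_hat,
                    "loglik_lambda0": est.loglik_at_zero,
                    "n": est.n,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "signal.tsv")

    def _categories():
        df = category_pgls(table, cov, config.categories, measures)
        _write_tsv(df, out / "category_pgls.tsv")

    def _scan(m):
        results, n_skipped = segmental_pgls(
            table, cov, m, window=config.window_size, stride=config.window_stride
        )
        if not results:
            _write_json(
                {"windows": 0, "skipped": n_skipped, "note": "all windows skipped"},
                out / f"scan_{m}.json",
            )
            return
        _write_tsv(pd.DataFrame([r.to_row() for r in results]), out / f"scan_{m}.tsv")
        _write_json({"windows": len(results), "skipped": n_skipped}, out / f"scan_{m}.json")

    def _smooth(m):
        fit = fit_smooth(topt, table.column(m), basis_dim=config.basis_dim)
        deriv = derivative(fit)
        _write_tsv(
            pd.DataFrame(
                {
                    "topt": fit.grid_temperature,
                    "fitted": fit.grid_fitted,
                    "derivative": deriv.values,
                }
            ),
            out / f"smooth_{m}.tsv",
        )
        _write_json(
            {
                "edf": fit.edf,
                "gcv": fit.gcv_score,
                "argmax_temperature": deriv.argmax_temperature,
            },
            out / f"smooth_{m}.json",
        )

    for m in measures:
        stage(f"bins_{m}", lambda m=m: _bins(m))
        if config.n_perm > 0:
            stage(f"dtest_{m}", lambda m=m: _dtest(m))
        else:
            manifest["stages"][f"dtest_{m}"] = {"status": "skipped", "reason": "n_perm=0"}
        stage(f"smooth_{m}", lambda m=m: _smooth(m))
        if config.run_scan:
            stage(f"scan_{m}", lambda m=m: _scan(m))
    stage("signal", _signal)
    stage("category_pgls", _categories)

    _write_json(manifest, out / "manifest.json")
    return manifest
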