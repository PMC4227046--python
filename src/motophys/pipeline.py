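"""End-to-end orchestration: simulate or load, measure, tabulate, compare."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ephys, morphometry, popstats, protocols
from .errors import AnalysisError
from .io import RunConfig, write_population
from .synthgen import GroupSpec, ModelCell, TreeSpec, generate_tree, sample_population
from .tables import morpho_rows
from .sampling import matched_truncnorm

log = logging.getLogger("motophys")


def parse_group(token: str) -> tuple[str, str]:
    try:
        genotype, pattern = token.split(":")
    except ValueError as exc:
        raise AnalysisError(f"group token {token!r} must be GENOTYPE:PATTERN") from exc
    return genotype, pattern


def simulate_population(config: RunConfig) -> list[ModelCell]:
    cells: list[ModelCell] = []
    rng = np.random.default_rng(config.seed)
    for token in config.groups:
        genotype, pattern = parse_group(token)
        spec = GroupSpec.from_tables(genotype, pattern)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cells.extend(sample_population(spec, config.n_cells, sub_seed))
    return cells


def features_table(cells: list[ModelCell], config: RunConfig,
                   include=("steps", "iv", "single_ap", "ramp")) -> pd.DataFrame:
    rows = []
    for cell in cells:
        try:
            feats = protocols.measure_cell(cell, include=include, mode=config.mode)
        except AnalysisError as exc:
            raise AnalysisError(f"cell {cell.id}, measurement stage: {exc}") from exc
        row = dataclasses.asdict(feats)
        row["pattern_true"] = cell.pattern
        rows.append(row)
        log.info("measured %s: rheobase=%.3f nA pattern=%s",
                 cell.id, feats.rheobase, feats.pattern)
    return pd.DataFrame(rows)


def morphometry_table(config: RunConfig, z_limit: float = morphometry.Z_LIMIT) -> pd.DataFrame:
    rows = []
    rng = np.random.default_rng(config.seed + 104729)
    for token in config.groups:
        genotype, pattern = parse_group(token)
        spec = TreeSpec.from_tables(genotype, pattern)
        soma_row = morpho_rows(genotype, pattern)["soma_area"]
        soma_dist = matched_truncnorm(soma_row.mean, soma_row.sd, soma_row.min, soma_row.max)
        for k in range(config.n_cells):
            seed = int(rng.integers(0, 2**31 - 1))
            morph, _truth = generate_tree(spec, seed)
            filtered = morphometry.apply_slice_filter(morph, z_limit)
            metrics = morphometry.compute_metrics(
                filtered, soma_area=float(soma_dist.rvs(1, rng)[0]))
            rows.append({
                "cell_id": f"{genotype}_{pattern}_{k:04d}",
                "genotype": genotype, "pattern": pattern,
                "n_primary": metrics.n_primary,
                "n_branch_points": metrics.n_branch_points,
                "total_length": metrics.total_length,
                "mean_dendritic_path": float(np.mean(metrics.dendritic_paths)),
                "mean_terminal_segment": float(np.mean(metrics.terminal_segment_lengths)),
                "soma_area": metrics.soma_area,
            })
    return pd.DataFrame(rows)


def comparison_report(table: pd.DataFrame, config: RunConfig) -> dict:
    """Per-pattern WT vs mSOD1 comparisons in the population-table layout."""
    numeric = [c for c in table.columns
               if pd.api.types.is_numeric_dtype(table[c]) and c not in ("pattern_true",)]
    report: dict = {"groups": {}, "tests": {}}
    summary = popstats.summarize(table, ["genotype", "pattern"], numeric)
    for key, row in summary.iterrows():
        report["groups"]["|".join(map(str, key))] = {
            prop: {stat: (None if pd.isna(row[(prop, stat)]) else float(row[(prop, stat)]))
                   for stat in ("mean", "sd", "min", "max", "n")}
            for prop in numeric
        }
    for pattern in sorted(table["pattern"].dropna().unique()):
        sub = table[table["pattern"] == pattern]
        wt = sub[sub["genotype"] == "WT"]
        ms = sub[sub["genotype"] == "mSOD1"]
        if len(wt) == 0 or len(ms) == 0:
            continue
        tests = {}
        for prop in numeric:
            a, b = wt[prop].dropna(), ms[prop].dropna()
            if len(a) and len(b):
                try:
                    tests[prop] = popstats.mann_whitney(a, b)
                except Exception:  # degenerate columns stay unreported
                    continue
        if {"G_in", "rheobase"} <= set(table.columns):
            wt_ok = wt.dropna(subset=["G_in", "rheobase"])
            ms_ok = ms.dropna(subset=["G_in", "rheobase"])
            if len(wt_ok) >= 3 and len(ms_ok) >= 3:
                cmp = popstats.compare_slopes(wt_ok["G_in"], wt_ok["rheobase"],
                                              ms_ok["G_in"], ms_ok["rheobase"])
                tests["rheobase_vs_conductance_slope"] = dataclasses.asdict(cmp)
        report["tests"][pattern] = tests
    return report


def run_pipeline(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate all configured groups, measure every cell, compare groups.

    Returns the population table and the report dict; both are also written
    under ``config.out_dir`` together with a provenance block.
    """
    cells = simulate_population(config)
    table = features_table(cells, config)
    report = comparison_report(table, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_population(table, out / "population.tsv")
    cfg = config.to_dict()
    provenance = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "n_cells": len(table),
    }
    report["provenance"] = provenance
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return table, report
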