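"""End-to-end orchestration: table -> PCA -> hulls -> null models -> tests.

A single :class:`RunConfig` (loadable from YAML) drives the full analysis.
One top-level seed is split into independent per-stage substreams with
``numpy.random.SeedSequence``, so adding or re-running a stage never perturbs
the randomness of the others, and identical config + seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .trait_data import (
    FuzzyTraitTable,
    default_dictionary,
    load_fuzzy_table,
    load_trait_dictionary,
    standardize_by_group,
    summarize_missing,
)
from .synthetic_data import SyntheticConfig, simulate_dataset
from .incomplete_pca import (
    fit_incomplete_pca,
    select_axes,
    trait_axis_correlations,
)
from .trait_space import group_axis_summary, group_volumes, null_model_test
from .group_tests import permanova, permdisp, run_relatedness_suite

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger("traitspace")

# substream indices: one per stochastic stage
_STREAM_SYNTH, _STREAM_NULL, _STREAM_PERM = 0, 1, 2


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int
    out_dir: str
    input_table: str | None = None  # TSV/CSV path; None -> synthetic
    dictionary_path: str | None = None  # None -> bundled dictionary
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    standardization: str = "max_code"
    axis_policy: str = "broken_stick"  # or "fixed"
    n_axes: int = 4  # used when axis_policy == "fixed"; cap otherwise
    correlation_threshold: float = 0.5
    trim_fraction: float = 0.95
    null_models: tuple[str, ...] = ("uniform", "normal", "permutation")
    null_reps: int = 999
    n_perms: int = 999
    taxon_col: str = "taxon"
    group_col: str = "group"
    full_group_col: str | None = None

    def validate(self) -> None:
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")
        if not 0.0 < self.trim_fraction <= 1.0:
            raise ValueError("trim_fraction must lie in (0, 1]")
        if self.axis_policy not in ("broken_stick", "fixed"):
            raise ValueError("axis_policy must be 'broken_stick' or 'fixed'")
        if self.n_axes < 2:
            raise ValueError("n_axes must be >= 2")


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    payload.update(overrides)
    if "null_models" in payload:
        payload["null_models"] = tuple(payload["null_models"])
    return RunConfig(**payload)


def _substream_seed(seed: int, stream: int) -> int:
    """Derive a bounded per-stage seed from the top-level seed."""
    child = np.random.SeedSequence([seed, stream])
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str, t0: float, **info) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, extras)


def _acquire_table(config: RunConfig) -> FuzzyTraitTable:
    if config.input_table is not None:
        dictionary = (
            load_trait_dictionary(config.dictionary_path)
            if config.dictionary_path
            else default_dictionary()
        )
        return load_fuzzy_table(
            config.input_table,
            dictionary,
            taxon_col=config.taxon_col,
            group_col=config.group_col,
            full_group_col=config.full_group_col,
        )
    synth = SyntheticConfig(
        seed=_substream_seed(config.seed, _STREAM_SYNTH), **config.synthetic
    )
    return simulate_dataset(synth)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write TSV outputs plus a JSON metadata sidecar."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    table = _acquire_table(config)
    missing = summarize_missing(table)
    _stage("load", t0, n_taxa=table.n_taxa, n_traits=table.n_traits,
           missing_percent=missing["percent"])

    std = standardize_by_group(table, mode=config.standardization)
    model = fit_incomplete_pca(std)
    selection = select_axes(model)
    if config.axis_policy == "fixed":
        k = min(config.n_axes, model.scores.shape[1])
    else:
        k = max(min(selection.retained, config.n_axes), 2)
    _stage("pca", t0, retained_broken_stick=selection.retained, axes_used=k)

    abbrs = table.dictionary.abbreviations
    axis_names = [f"axis{a + 1}" for a in range(k)]
    pd.DataFrame(
        {"taxon": table.taxon_ids, "group": table.groups}
        | {name: model.scores[:, a] for a, name in enumerate(axis_names)}
    ).to_csv(out / "scores.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"trait": abbrs}
        | {name: model.loadings[:, a] for a, name in enumerate(axis_names)}
    ).to_csv(out / "loadings.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "axis": np.arange(1, model.eigenvalues.size + 1),
            "eigenvalue": model.eigenvalues,
            "variance_proportion": model.variance_proportion,
            "broken_stick": np.concatenate(
                [selection.broken_stick,
                 np.zeros(model.eigenvalues.size - selection.broken_stick.size)]
            ),
        }
    ).to_csv(out / "eigenvalues.tsv", sep="\t", index=False)

    corr = trait_axis_correlations(std, model, k, config.correlation_threshold)
    pd.DataFrame(
        {"trait": abbrs}
        | {name: corr.r[:, a] for a, name in enumerate(axis_names)}
    ).to_csv(out / "correlations.tsv", sep="\t", index=False)
    _stage("correlations", t0, axes=k)

    scores_k = model.scores[:, :k]
    moments = group_axis_summary(scores_k, table.groups, n_axes=k)
    pd.DataFrame(
        [
            {"group": g, "n_taxa": moments.n_taxa[g]}
            | {f"mean_{nm}": moments.axis_means[g][a] for a, nm in enumerate(axis_names)}
            | {f"var_{nm}": moments.axis_variances[g][a] for a, nm in enumerate(axis_names)}
            for g in moments.group_names
        ]
    ).to_csv(out / "group_moments.tsv", sep="\t", index=False)

    vols = group_volumes(scores_k, table.groups, table.taxon_ids)
    rows = [
        {
            "group": "whole_assemblage",
            "n_taxa": table.n_taxa,
            "hull_volume": vols.whole_volume,
            "standardized_volume_percent": vols.whole_standardized_percent,
        }
    ] + [
        {
            "group": g,
            "n_taxa": vols.n_taxa[g],
            "hull_volume": vols.hull_volume[g],
            "standardized_volume_percent": vols.standardized_volume_percent[g],
        }
        for g in vols.group_names
    ]
    pd.DataFrame(rows).to_csv(out / "group_volumes.tsv", sep="\t", index=False)
    _stage("hulls", t0, whole_volume=round(vols.whole_volume, 4))

    null_seed = _substream_seed(config.seed, _STREAM_NULL)
    null_rows = []
    for m in config.null_models:
        res = null_model_test(
            scores_k, m, n_reps=config.null_reps,
            fraction=config.trim_fraction, seed=null_seed,
        )
        null_rows.append(
            {
                "model": m,
                "n_reps": res.n_reps,
                "observed_volume": res.observed_volume,
                "mean_null_volume": float(np.mean(res.null_volumes)),
                "occupancy_percent": res.occupancy_percent,
                "p_value": res.p_value,
            }
        )
    pd.DataFrame(null_rows).to_csv(out / "nullmodel.tsv", sep="\t", index=False)
    _stage("null_models", t0, models=",".join(config.null_models))

    perm_seed = _substream_seed(config.seed, _STREAM_PERM)
    test_rows = []
    if table.full_groups is not None and set(table.full_groups) != set(table.groups):
        suite = run_relatedness_suite(
            scores_k, table.groups, table.full_groups,
            n_perms=config.n_perms, seed=perm_seed,
        )
        for key, res in suite.items():
            pa, pdis = res["permanova"], res["permdisp"]
            test_rows.append(
                {
                    "labels": key, "n_taxa": res["n_taxa"], "n_groups": res["n_groups"],
                    "permanova_F": pa.pseudo_F, "permanova_R2": pa.R2,
                    "permanova_df": pa.df_between, "permanova_p": pa.p_value,
                    "permdisp_F": pdis.F, "permdisp_p": pdis.p_value,
                }
            )
    else:
        pa = permanova(scores_k, table.groups, n_perms=config.n_perms, seed=perm_seed)
        pdis = permdisp(scores_k, table.groups, n_perms=config.n_perms, seed=perm_seed)
        test_rows.append(
            {
                "labels": "pooled", "n_taxa": table.n_taxa,
                "n_groups": len(set(table.groups)),
                "permanova_F": pa.pseudo_F, "permanova_R2": pa.R2,
                "permanova_df": pa.df_between, "permanova_p": pa.p_value,
                "permdisp_F": pdis.F, "permdisp_p": pdis.p_value,
            }
        )
    pd.DataFrame(test_rows).to_csv(out / "group_tests.tsv", sep="\t", index=False)
    _stage("group_tests", t0)

    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_taxa": table.n_taxa,
        "n_traits": table.n_traits,
        "missing_cells": missing,
        "axes_used": k,
        "broken_stick_retained": int(selection.retained),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    return out
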