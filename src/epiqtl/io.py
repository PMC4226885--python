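"""Readers and writers for the package's plain-text file formats.

* map CSV: header ``marker,chromosome,position_cM``, chromosomes ordered by
  first appearance;
* cross CSV: header ``id,phenotype,<marker names...>``, genotype codes
  ``A`` (homozygous), ``H`` (heterozygous), ``-`` (missing);
* architecture YAML/JSON: keys ``map``, ``qtl``, ``interactions``,
  ``residual_sd``;
* model report JSON, profile CSV, metrics CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genetic_map import HET, HOM, MISSING, GeneticMap, Locus
from .mim import BackcrossData, FitResult, MIMModel, variance_partition
from .simulator import Architecture

__all__ = [
    "read_map",
    "write_map",
    "read_cross",
    "write_cross",
    "read_architecture",
    "write_architecture",
    "model_report",
    "write_model_report",
    "write_profile",
    "write_metrics",
]

_CODE_TO_INT = {"A": HOM, "H": HET, "-": MISSING}
_INT_TO_CODE = {HOM: "A", HET: "H", MISSING: "-"}


def read_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path)
    required = ["marker", "chromosome", "position_cM"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"map file must have header {','.join(required)}")
    try:
        return GeneticMap.from_records(
            (str(r.marker), str(r.chromosome), float(r.position_cM))
            for r in df.itertuples()
        )
    except ValueError as exc:
        raise ValueError(f"invalid map file {path}: {exc}") from exc


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = []
    for chrom, names, pos in zip(gmap.chromosomes, gmap.marker_names, gmap.positions):
        for name, p in zip(names, pos):
            rows.append({"marker": name, "chromosome": chrom, "position_cM": p})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cross(path: str | Path, gmap: GeneticMap) -> BackcrossData:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["id", "phenotype"]:
        raise ValueError("cross file must start with columns id,phenotype")
    file_markers = list(df.columns[2:])
    map_markers = list(gmap.all_marker_names())
    if file_markers != map_markers:
        if sorted(file_markers) != sorted(map_markers):
            missing = set(map_markers) - set(file_markers)
            extra = set(file_markers) - set(map_markers)
            raise ValueError(
                f"cross/map marker mismatch (missing {sorted(missing)[:5]}, "
                f"unknown {sorted(extra)[:5]})"
            )
        import warnings

        warnings.warn("cross marker columns permuted; reordering to map order")
        df = df[["id", "phenotype"] + map_markers]
    try:
        y = df["phenotype"].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"unparseable phenotype in {path}: {exc}") from exc
    geno = np.empty((len(df), len(map_markers)), dtype=np.int8)
    for j, marker in enumerate(map_markers):
        col = df[marker].fillna("-")
        for i, code in enumerate(col):
            try:
                geno[i, j] = _CODE_TO_INT[code.strip()]
            except KeyError:
                raise ValueError(
                    f"bad genotype code {code!r} at row {i + 2}, column {marker!r}"
                ) from None
    return BackcrossData(phenotypes=y, genotypes=geno, map=gmap)


def write_cross(data: BackcrossData, path: str | Path,
                ids: list[str] | None = None) -> None:
    markers = data.map.all_marker_names()
    rows = []
    for i in range(data.n):
        row = {"id": ids[i] if ids else f"ind{i + 1}",
               "phenotype": repr(float(data.phenotypes[i]))}
        for j, m in enumerate(markers):
            row[m] = _INT_TO_CODE[int(data.genotypes[i, j])]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_architecture(path: str | Path) -> Architecture:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    gmap = GeneticMap.from_records(
        (m["marker"], m["chromosome"], m["position_cM"]) for m in payload["map"]
    )
    qtl = tuple(Locus(str(q["chrom"]), float(q["pos_cM"])) for q in payload["qtl"])
    effects = np.array([float(q.get("effect", 0.0)) for q in payload["qtl"]])
    pairs = tuple(
        (int(i["k"]) - 1, int(i["l"]) - 1) for i in payload.get("interactions", [])
    )
    gammas = np.array([float(i["effect"]) for i in payload.get("interactions", [])])
    return Architecture(
        map=gmap, qtl=qtl, main_effects=effects, interactions=pairs,
        interaction_effects=gammas, sigma=float(payload.get("residual_sd", 1.0)),
    )


def write_architecture(arch: Architecture, path: str | Path) -> None:
    gmap = arch.map
    payload = {
        "map": [
            {"marker": n, "chromosome": c, "position_cM": float(p)}
            for c, names, pos in zip(gmap.chromosomes, gmap.marker_names, gmap.positions)
            for n, p in zip(names, pos)
        ],
        "qtl": [
            {"chrom": loc.chromosome, "pos_cM": float(loc.position),
             "effect": float(a)}
            for loc, a in zip(arch.qtl, arch.main_effects)
        ],
        "interactions": [
            {"k": k + 1, "l": l + 1, "effect": float(g)}
            for (k, l), g in zip(arch.interactions, arch.interaction_effects)
        ],
        "residual_sd": float(arch.sigma),
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def model_report(fit: FitResult) -> dict:
    """JSON-serializable summary of a fitted MIM model (1-based QTL indices)."""
    model = fit.model
    part = variance_partition(fit)
    return {
        "n_qtl": model.n_qtl,
        "qtl": [
            {"index": k + 1, "chrom": loc.chromosome, "pos_cM": float(loc.position),
             "main_effect": float(model.a[k])}
            for k, loc in enumerate(model.qtl)
        ],
        "interactions": [
            {"k": k + 1, "l": l + 1, "effect": float(g)}
            for (k, l), g in zip(model.interactions, model.gamma)
        ],
        "mu": float(model.mu),
        "sigma2": float(model.sigma2),
        "loglik": float(fit.loglik),
        "converged": bool(fit.converged),
        "r_squared": part["r_squared"],
        "variance_components": part["components"],
        "covariance_components": part["covariances"],
    }


def write_model_report(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_report(fit), indent=2))


def write_profile(rows: list[tuple[str, float, float]], path: str | Path,
                  value_name: str = "statistic") -> None:
    pd.DataFrame(rows, columns=["chrom", "pos_cM", value_name]).to_csv(
        path, index=False
    )


def write_metrics(table, path_prefix: str | Path) -> None:
    """Write a MetricsTable as <prefix>_qtl.csv, <prefix>_interactions.csv and
    <prefix>_summary.json."""
    prefix = Path(path_prefix)
    table.qtl.to_csv(prefix.with_name(prefix.name + "_qtl.csv"), index=False)
    table.interactions.to_csv(
        prefix.with_name(prefix.name + "_interactions.csv"), index=False
    )
    summary = {
        "fpr": table.fpr,
        "fpr_interactions": table.fpr_i,
        "mean_n_qtl": table.mean_n_qtl,
        "n_replicates": table.n_replicates,
        "n_failed": table.n_failed,
        "model_size_counts": {str(k): v for k, v in table.model_size_counts.items()},
        "interaction_size_counts": {
            str(k): v for k, v in table.interaction_size_counts.items()
        },
    }
    prefix.with_name(prefix.name + "_summary.json").write_text(
        json.dumps(summary, indent=2)
    )
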