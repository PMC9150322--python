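"""Readers and writers for the on-disk formats.

Expression matrices are samples x genes TSV with a header of gene ids and a
first column of sample ids; clinical tables are CSV with survival time,
event status and environmental covariates; gene sets use the GMT format.
All joins are inner joins on sample id with logged drop counts and no silent
imputation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .coxcore import SurvivalDataset
from .pathways import PathwayCollection

__all__ = [
    "read_expression",
    "read_dataset",
    "read_gmt",
    "restrict_pathways",
    "export_dataset",
    "write_gmt",
    "write_selection",
    "write_metadata",
]

logger = logging.getLogger(__name__)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    bad = df.columns[~df.dtypes.apply(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(
            f"non-numeric expression column(s) in {path}: {list(bad[:5])}"
        )
    return df


def read_dataset(
    expression_path: str | Path,
    clinical_path: str | Path,
    env_columns: list[str],
    time_column: str = "time",
    status_column: str = "status",
    id_column: str = "id",
) -> SurvivalDataset:
    """Inner-join expression and clinical tables on sample id.

    Rows with missing outcome or environment values are rejected with a
    named report (no silent imputation). Transposed expression input
    (gene rows) is detected by id overlap and rejected with guidance.
    """
    expr = read_expression(expression_path)
    clin = pd.read_csv(clinical_path, float_precision="round_trip")
    if id_column not in clin.columns:
        raise ValueError(f"clinical table lacks id column {id_column!r}")
    clin[id_column] = clin[id_column].astype(str)
    clin = clin.set_index(id_column)

    row_overlap = len(clin.index.intersection(expr.index))
    col_overlap = len(clin.index.intersection(expr.columns.astype(str)))
    if col_overlap > row_overlap:
        raise ValueError(
            "expression matrix appears transposed (sample ids found in its "
            "header); provide samples as rows and genes as columns"
        )

    for col in [time_column, status_column, *env_columns]:
        if col not in clin.columns:
            raise ValueError(f"clinical table lacks column {col!r}")
    missing_mask = clin[[time_column, status_column, *env_columns]].isna().any(axis=1)
    if missing_mask.any():
        raise ValueError(
            "missing outcome/environment values for samples: "
            + ", ".join(map(str, clin.index[missing_mask][:10]))
        )

    common = clin.index[clin.index.isin(expr.index)]  # keep clinical row order
    dropped = (len(clin) - len(common)) + (len(expr) - len(common))
    if dropped:
        logger.info("dropped %d unmatched sample rows during join", dropped)
    if len(common) == 0:
        raise ValueError("no overlapping sample ids between the two tables")
    clin = clin.loc[common]
    expr = expr.loc[common]

    status = clin[status_column].to_numpy()
    if not np.isin(status, (0, 1)).all():
        bad_ids = clin.index[~np.isin(status, (0, 1))]
        raise ValueError(f"status must be 0/1; offending samples: {list(bad_ids[:5])}")
    return SurvivalDataset(
        time=clin[time_column].to_numpy(float),
        event=status.astype(int),
        E=clin[env_columns].to_numpy(float),
        X=expr.to_numpy(float),
        env_names=tuple(env_columns),
        gene_names=tuple(map(str, expr.columns)),
    )


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file (``name<TAB>description<TAB>gene1<TAB>...``).

    Descriptions are discarded; duplicate genes within a set are removed
    with a warning; a line with fewer than three fields is rejected with
    its line number.
    """
    names: list[str] = []
    members: list[tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name = fields[0]
            genes: list[str] = []
            seen = set()
            dup = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dup += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dup:
                logger.warning(
                    "%s:%d: removed %d duplicate gene(s) in set %s",
                    path, lineno, dup, name,
                )
            names.append(name)
            members.append(tuple(genes))
    return PathwayCollection(group_names=tuple(names), members=tuple(members))


def restrict_pathways(
    pathways: PathwayCollection,
    universe: list[str] | tuple[str, ...],
    ungrouped: str = "discard",
    pooled_name: str = "_ungrouped",
) -> PathwayCollection:
    """Drop member genes absent from the expression universe (logged count),
    remove sets emptied by the filter, and either discard genes mapped to no
    set or pool them into one extra group."""
    if ungrouped not in ("discard", "pool"):
        raise ValueError("ungrouped must be 'discard' or 'pool'")
    uni = set(universe)
    names, members = [], []
    removed = 0
    for nm, genes in zip(pathways.group_names, pathways.members):
        kept = tuple(g for g in genes if g in uni)
        removed += len(genes) - len(kept)
        if kept:
            names.append(nm)
            members.append(kept)
    if removed:
        logger.info("dropped %d gene memberships absent from expression", removed)
    covered = {g for m in members for g in m}
    if ungrouped == "pool":
        rest = tuple(g for g in universe if g not in covered)
        if rest:
            names.append(pooled_name)
            members.append(rest)
    if not names:
        raise ValueError("no gene set survives filtering")
    return PathwayCollection(group_names=tuple(names), members=tuple(members))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def export_dataset(
    data: SurvivalDataset, outdir: str | Path, prefix: str = "cohort"
) -> dict[str, Path]:
    """Write the survival CSV (id, time, status, environments) and the
    samples x genes expression TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [f"S{i + 1}" for i in range(data.n)]
    clin = pd.DataFrame({"id": ids, "time": data.time, "status": data.event})
    for j, env in enumerate(data.env_names):
        clin[env] = data.E[:, j]
    clin_path = outdir / f"{prefix}_clinical.csv"
    # %.17g keeps the round trip bit-exact for doubles
    clin.to_csv(clin_path, index=False, float_format="%.17g")
    expr = pd.DataFrame(data.X, index=pd.Index(ids, name="id"),
                        columns=list(data.gene_names))
    expr_path = outdir / f"{prefix}_expression.tsv"
    expr.to_csv(expr_path, sep="\t", float_format="%.17g")
    return {"clinical": clin_path, "expression": expr_path}


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for nm, genes in zip(pathways.group_names, pathways.members):
            fh.write("\t".join([nm, "na", *genes]) + "\n")


def write_selection(selection, model, pathways: PathwayCollection,
                    outdir: str | Path) -> dict[str, Path]:
    """Selection TSV (feature, type, group, coefficient) and group p-value TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_groups: dict[str, list[str]] = {}
    for nm, genes in zip(pathways.group_names, pathways.members):
        for g in genes:
            gene_groups.setdefault(g, []).append(nm)
    rows = []
    for nm, b in zip(model.feature_names, model.coef):
        if ":" in nm:
            ftype, gene = "GxE", nm.split(":", 1)[1]
        elif nm in gene_groups:
            ftype, gene = "G", nm
        else:
            ftype, gene = "E", None
        grp = ";".join(gene_groups.get(gene, [])) if gene else ""
        rows.append({"feature": nm, "type": ftype, "group": grp, "coefficient": b})
    sel_path = outdir / "selection.tsv"
    pd.DataFrame(rows).to_csv(sel_path, sep="\t", index=False)
    pv_path = outdir / "group_pvalues.tsv"
    pd.DataFrame(
        [{"group": g, "pvalue": p} for g, p in selection.group_pvalues.items()]
    ).to_csv(pv_path, sep="\t", index=False)
    return {"selection": sel_path, "group_pvalues": pv_path}


def write_metadata(outdir: str | Path, **payload) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "run_metadata.json"

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump({"version": __version__, **payload}, fh, indent=2,
                  default=_default)
    return path
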