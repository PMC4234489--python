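"""Readers and writers for the pipeline's tab-separated text formats.

All formats are TSV with a header row, "." as decimal point and no
thousands separators:

* expression: genes in rows, one gene-identifier column (default
  ``gene_id``), remaining columns are samples;
* phenotypes: columns ``sample, status, grade, type, stage`` with
  free-text clinical values (G1/G2/G3, T1/T2, IA/IB/IC/II/...);
* gene sets: standard GMT (name TAB description TAB member...);
* hub-score tables: columns ``gene, trait, module, f, K, GS``.

The package ships ``data/ec_hub_genes.tsv``, a transcription of the
published hub-gene score table from the endometrial-cancer co-expression
study this pipeline re-implements (19 gene-trait entries).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from cohub.datatypes import ExpressionMatrix, GeneSetCollection, HubScoreRow, PhenotypeTable

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A text input does not follow its declared dialect."""


# ---------------------------------------------------------------------------
# expression matrices

def read_expression(
    path: str | Path,
    id_column: str = "gene_id",
    platform_label: str = "P1",
    platform_map: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    Duplicate gene identifiers are collapsed by keeping the highest-variance
    row; rows with any missing value are dropped (the drop count is logged).

    Parameters
    ----------
    path : str or Path
        Tab-separated file; header row holds sample identifiers.
    id_column : str
        Name of the gene-identifier column.
    platform_label : str
        Platform label assigned to every sample not covered by
        ``platform_map``.
    platform_map : dict, optional
        Explicit sample -> platform labels (for multi-platform files).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_column not in df.columns:
        raise FormatError(f"{path}: missing identifier column '{id_column}'")
    sample_cols = [c for c in df.columns if c != id_column]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")

    values = pd.DataFrame(index=df.index)
    for col in sample_cols:
        raw = df[col]
        # pd.to_numeric validates; numpy's strtod-based parser is used for
        # the actual conversion because it round-trips full precision
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            i = int(bad.idxmax())
            raise FormatError(
                f"{path}: non-numeric value '{raw[i]}' for gene "
                f"'{df[id_column][i]}', sample column '{col}'"
            )
        exact = np.full(len(raw), np.nan)
        ok = ~num.isna().to_numpy()
        exact[ok] = raw.to_numpy()[ok].astype(float)
        values[col] = exact

    gene_ids = df[id_column].astype(str)
    complete = ~values.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("%s: dropped %d gene rows with missing values", path, n_dropped)
    values = values[complete]
    gene_ids = gene_ids[complete]

    # collapse duplicate gene IDs: keep the maximum-variance row
    if gene_ids.duplicated().any():
        variances = values.var(axis=1, ddof=1).fillna(0.0)
        order = variances.to_numpy()
        keep = (
            pd.DataFrame({"gene": gene_ids.to_numpy(), "var": order}, index=values.index)
            .sort_values("var", kind="stable")
            .drop_duplicates("gene", keep="last")
            .index
        )
        keep = values.index[values.index.isin(keep)]  # restore file order
        values = values.loc[keep]
        gene_ids = gene_ids.loc[keep]

    samples = list(values.columns)
    if platform_map is None:
        platform = [platform_label] * len(samples)
    else:
        platform = [platform_map.get(s, platform_label) for s in samples]
    return ExpressionMatrix(
        gene_ids=list(gene_ids),
        sample_ids=samples,
        platform=platform,
        values=values.to_numpy(dtype=float),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path, id_column: str = "gene_id") -> None:
    """Write a genes x samples expression TSV (full float precision)."""
    df = matrix.to_frame()
    df.index.name = id_column
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_platform_map(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the sample -> platform assignment as a two-column TSV."""
    pd.DataFrame({"sample": matrix.sample_ids, "platform": matrix.platform}).to_csv(
        path, sep="\t", index=False
    )


def read_platform_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "platform"} <= set(df.columns):
        raise FormatError(f"{path}: platform map needs columns sample, platform")
    return dict(zip(df["sample"], df["platform"]))


# ---------------------------------------------------------------------------
# phenotypes

_STATUS_CODES = {"case": 1, "control": 0, "1": 1, "0": 0, "tumor": 1, "normal": 0}


def _parse_grade(value: str) -> float:
    # G3 (poorly differentiated) vs G1 (well differentiated); the
    # intermediate G2 is excluded from the binary contrast.
    v = value.strip().upper()
    if v in {"G1", "LOW", "0"}:
        return 0.0
    if v in {"G3", "HIGH", "1"}:
        return 1.0
    return np.nan


def _parse_type(value: str) -> float:
    v = value.strip().upper()
    if v in {"T1", "I", "1", "TYPE I"}:
        return 0.0
    if v in {"T2", "II", "2", "TYPE II"}:
        return 1.0
    return np.nan


_LATE_STAGES = {"IC", "II", "IIA", "IIB", "III", "IIIA", "IIIB", "IIIC", "IV", "IVA", "IVB", "LATE"}


def _parse_stage(value: str) -> float:
    # dichotomy: IA/IB early versus IC-or-later late
    v = value.strip().upper()
    if v in {"IA", "IB", "I", "EARLY", "0"}:
        return 0.0
    if v in _LATE_STAGES or v == "1":
        return 1.0
    return np.nan


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a sample phenotype TSV with clinical free-text trait values.

    Grade maps G1 -> low, G3 -> high, G2 -> unknown; stage maps IA/IB ->
    early and IC-or-later -> late; type maps T1/T2 -> I/II.  Blank or
    unparseable values become unknown (with a warning).  Controls always
    carry unknown tumor traits.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["sample", "status", "grade", "type", "stage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id '{dup}'")

    status = []
    for s in df["status"]:
        code = _STATUS_CODES.get(s.strip().lower())
        if code is None:
            raise FormatError(f"{path}: unrecognized status value '{s}'")
        status.append(code)
    status = np.array(status, dtype=int)

    parsed = {}
    for name, parse in (("grade", _parse_grade), ("type", _parse_type), ("stage", _parse_stage)):
        col = df[name].to_numpy()
        vals = np.array([parse(v) for v in col])
        odd = [v for v, x in zip(col, vals) if np.isnan(x) and v.strip() != ""]
        unexpected = [v for v in odd if v.strip().upper() not in {"G2", "UNKNOWN", "NA"}]
        if unexpected:
            logger.warning(
                "%s: %d unparseable %s values (e.g. '%s') mapped to unknown",
                path, len(unexpected), name, unexpected[0],
            )
        vals[status == 0] = np.nan  # controls have no tumor traits
        parsed[name] = vals

    return PhenotypeTable(
        sample_ids=list(df["sample"]),
        status=status,
        grade=parsed["grade"],
        type=parsed["type"],
        stage=parsed["stage"],
    )


_TRAIT_WRITE = {
    "grade": {0.0: "G1", 1.0: "G3"},
    "type": {0.0: "T1", 1.0: "T2"},
    "stage": {0.0: "IA", 1.0: "IC"},
}


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    """Write phenotypes in the clinical dialect ``read_phenotypes`` accepts."""
    rows = []
    for i, sample in enumerate(table.sample_ids):
        row = {"sample": sample, "status": "case" if table.status[i] else "control"}
        for name in ("grade", "type", "stage"):
            v = table.trait(name)[i]
            row[name] = "" if np.isnan(v) else _TRAIT_WRITE[name][v]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT gene-set file (name TAB description TAB members...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set '{name}' has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# hub-score tables

def read_hub_table(path: str | Path, B: int = 1000) -> list[HubScoreRow]:
    """Read a hub-score TSV (gene, trait, module, f, K, GS) with validation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "trait", "module", "f", "K", "GS"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            HubScoreRow(
                gene=str(rec.gene),
                trait=str(rec.trait),
                module=str(rec.module),
                f=int(rec.f),
                K=float(rec.K),
                GS=float(rec.GS),
                B=B,
            )
        )
    return rows


def write_hub_table(rows: list[HubScoreRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": r.gene, "trait": r.trait, "module": r.module, "f": r.f, "K": r.K, "GS": r.GS}
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def load_reference_hub_table() -> list[HubScoreRow]:
    """The published endometrial-cancer hub-gene table shipped with cohub
    (19 gene-trait entries with their f, K and GS scores)."""
    with resources.as_file(resources.files("cohub").joinpath("data/ec_hub_genes.tsv")) as p:
        return read_hub_table(p)
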