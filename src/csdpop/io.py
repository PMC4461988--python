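"""File formats: Genepop and a genotype-CSV dialect, plus report writers.

Genepop: title line, one locus name per line (or comma-separated),
``POP`` blocks, individual lines ``id , 0101 0202 ...`` with 2- or
3-digit allele codes; ``00``/``000`` encodes a missing allele.  Population
blocks map to field labels; the region level comes from a separate
hierarchy map (field,region CSV) since Genepop has no second level.

CSV dialect: header ``id,region,field,<locus...>``; calls ``A1/A2`` with
integer allele codes; missing ``./.``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_hierarchy_map",
    "write_reports",
]


class GenepopParseError(ValueError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def read_genepop(
    path: str | Path,
    field_names: list[str] | None = None,
    region_of: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a Genepop file into a genotype matrix.

    POP blocks become fields named ``pop1``, ``pop2``, ... unless
    ``field_names`` is given.  Without a ``region_of`` map every field is
    placed in a single region ``all``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file", 1)
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        for name in lines[i].replace(",", " ").split():
            locus_ids.append(name)
        i += 1
    if not locus_ids:
        raise GenepopParseError("no locus names before first POP", i + 1)

    individuals: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    field_of: dict[str, str] = {}
    pop_index = 0
    code_width: int | None = None
    while i < len(lines):
        line = lines[i]
        if line.strip().upper() == "POP":
            pop_index += 1
            i += 1
            continue
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise GenepopParseError("expected 'id , genotypes' line", i + 1)
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != len(locus_ids):
            raise GenepopParseError(
                f"{len(tokens)} genotypes for {len(locus_ids)} declared loci", i + 1
            )
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopParseError(f"bad genotype code {tok!r}", i + 1)
            w = len(tok) // 2
            if code_width is None:
                code_width = w
            elif code_width != w:
                raise GenepopParseError(
                    f"mixed allele-code widths ({code_width} and {w} digits)", i + 1
                )
            a, b = int(tok[:w]), int(tok[w:])
            row.append((MISSING, MISSING) if a == 0 or b == 0 else (a, b))
        if ind_id in field_of:
            raise GenepopParseError(f"duplicate individual id {ind_id!r}", i + 1)
        fname = (
            field_names[pop_index - 1]
            if field_names and pop_index <= len(field_names)
            else f"pop{pop_index}"
        )
        individuals.append(ind_id)
        field_of[ind_id] = fname
        calls.append(row)
        i += 1
    if not individuals:
        raise GenepopParseError("no individuals found", len(lines))
    fields = sorted(set(field_of.values()))
    if region_of is None:
        region_of = {f: "all" for f in fields}
    return GenotypeMatrix(
        calls=np.array(calls, dtype=np.int16),
        individual_ids=individuals,
        locus_ids=locus_ids,
        field_of=field_of,
        region_of=region_of,
    )


def write_genepop(matrix: GenotypeMatrix, path: str | Path, title: str = "csdpop export") -> None:
    """Write a genotype matrix as Genepop (one POP block per field)."""
    width = 3 if int(matrix.calls.max(initial=0)) > 99 else 2
    zero = "0" * width
    out = [title]
    out.extend(matrix.locus_ids)
    for f in matrix.field_labels():
        out.append("POP")
        sub = matrix.field_subset(f)
        for idx, ind in enumerate(sub.individual_ids):
            codes = []
            for a, b in sub.calls[idx]:
                if a == MISSING:
                    codes.append(zero + zero)
                else:
                    codes.append(f"{a:0{width}d}{b:0{width}d}")
            out.append(f"{ind} , " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read the genotype-CSV dialect (id,region,field,<loci>)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "region", "field"):
        if col not in df.columns:
            raise ValueError(f"genotype CSV must have an {col!r} column")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicated individual id {dup!r}")
    locus_ids = [c for c in df.columns if c not in ("id", "region", "field")]
    n, L = len(df), len(locus_ids)
    calls = np.full((n, L, 2), MISSING, dtype=np.int16)
    for j, locus in enumerate(locus_ids):
        for i, val in enumerate(df[locus]):
            val = str(val).strip()
            if val in ("./.", "", "nan"):
                continue
            a, b = val.split("/")
            calls[i, j] = (int(a), int(b))
    field_of = dict(zip(df["id"], df["field"]))
    region_of = {}
    for fld, reg in zip(df["field"], df["region"]):
        if fld in region_of and region_of[fld] != reg:
            raise ValueError(f"field {fld!r} mapped to multiple regions")
        region_of[fld] = reg
    return GenotypeMatrix(calls, list(df["id"]), locus_ids, field_of, region_of)


def write_genotype_csv(matrix: GenotypeMatrix, path: str | Path) -> None:
    rows = []
    for i, ind in enumerate(matrix.individual_ids):
        fld = matrix.field_of[ind]
        row = {"id": ind, "region": matrix.region_of[fld], "field": fld}
        for j, locus in enumerate(matrix.locus_ids):
            a, b = matrix.calls[i, j]
            row[locus] = "./." if a == MISSING else f"{a}/{b}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_hierarchy_map(path: str | Path) -> dict[str, str]:
    """Read a field,region CSV into a field -> region map."""
    df = pd.read_csv(path, dtype=str)
    if not {"field", "region"}.issubset(df.columns):
        raise ValueError("hierarchy map must have 'field' and 'region' columns")
    return dict(zip(df["field"], df["region"]))


def write_reports(results: dict, outdir: str | Path) -> list[Path]:
    """Write analysis results as CSV tables.

    Recognized keys: ``per_field`` (per-field heterozygosity and F_IS),
    ``pairwise_fst``/``pairwise_p`` (combined into one matrix with F_ST
    below and p-values above the diagonal), ``amova``, ``fstats``,
    ``locus_reports``, ``dmp``.  Unknown keys are written as-is when they
    are DataFrames.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = outdir / name
        df.to_csv(p, index=index)
        written.append(p)

    results = dict(results)
    if "pairwise_fst" in results and "pairwise_p" in results:
        fst = results.pop("pairwise_fst")
        pval = results.pop("pairwise_p")
        combined = fst.copy()
        for i, a in enumerate(combined.index):
            for j, b in enumerate(combined.columns):
                if j > i:
                    combined.iloc[i, j] = pval.iloc[i, j]
                elif i == j:
                    combined.iloc[i, j] = np.nan
        save(combined, "pairwise_fst.csv", index=True)
    if "fstats" in results:
        r = results.pop("fstats")
        df = pd.DataFrame(
            {
                "statistic": ["f_is", "f_st", "f_it"],
                "estimate": [r.f_is, r.f_st, r.f_it],
                "ci_low": [r.ci.get(s, (np.nan, np.nan))[0] for s in ("f_is", "f_st", "f_it")],
                "ci_high": [r.ci.get(s, (np.nan, np.nan))[1] for s in ("f_is", "f_st", "f_it")],
            }
        )
        save(df, "fstats.csv")
    if "amova" in results:
        save(results.pop("amova"), "amova.csv", index=True)
    if "per_field" in results:
        save(results.pop("per_field"), "per_field.csv")
    if "locus_reports" in results:
        save(results.pop("locus_reports"), "locus_reports.csv")
    if "dmp" in results:
        save(results.pop("dmp"), "dmp.csv")
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            save(value, f"{key}.csv")
    return written
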