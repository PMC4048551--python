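"""On-disk formats.

The package reads and writes plain-text formats only:

* **PLINK text** ``.ped``/``.map`` pairs for unphased genotypes. The breed /
  group label rides in the family-ID column, per PLINK convention. Genotypes
  are recoded as counts of the alphabetically smallest allele observed at
  each marker; unknown alleles ("0") become missing.
* **Haplotype TSV** — one row per phased haplotype:
  ``haplotype_id<TAB>breed<TAB>allele...`` with alleles ``0``/``1``/``.``.
* **Painting TSV** — one row per haplotype of posterior probabilities of
  copying from donor panel A.
* **Block table** — BED5-like (chrom, start, end, label, haplotype_id),
  0-based half-open, with a ``#``-prefixed header; per-chromosome marker
  spans are carried on ``#span`` header lines so the file round-trips.
* **Result tables** — TSV with floats at 6 significant digits.
* **Config** — flat YAML ``key: value`` mappings.

All coordinates on disk are 0-based half-open.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    MISSING,
    AncestryPainting,
    Block,
    BlockSet,
    FormatError,
    GenotypeTable,
    HaplotypePanel,
    MarkerMap,
    chrom_sort_key,
)

# ---------------------------------------------------------------------------
# PLINK text genotypes


def read_map(map_path: str) -> MarkerMap:
    """Read a 4-column PLINK .map (chrom, name, cM, bp), canonically sorted."""
    chroms: list[str] = []
    names: list[str] = []
    cms: list[float] = []
    bps: list[int] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 columns, found {len(fields)}"
                )
            chroms.append(fields[0])
            names.append(fields[1])
            try:
                cms.append(float(fields[2]))
                bps.append(int(fields[3]))
            except ValueError as exc:
                raise FormatError(f"{map_path}:{lineno}: {exc}") from None
    cm = np.asarray(cms, dtype=float)
    marker_map = MarkerMap(
        chrom=np.asarray(chroms, dtype=object),
        name=np.asarray(names, dtype=object),
        pos_bp=np.asarray(bps, dtype=np.int64),
        pos_cm=None if np.all(cm == 0) else cm,
    )
    marker_map, _ = marker_map.canonicalize()
    marker_map.validate()
    return marker_map


def read_genotypes(ped_path: str, map_path: str) -> tuple[GenotypeTable, MarkerMap]:
    """Read a PLINK-text .ped/.map pair.

    Returns the genotype table in canonical (chrom, pos_bp) marker order.
    The family-ID column is interpreted as the breed label. Markers with more
    than two observed alleles raise :class:`FormatError`.
    """
    # read the map unsorted first so we can permute ped columns to match
    raw_chrom: list[str] = []
    raw_name: list[str] = []
    raw_cm: list[float] = []
    raw_bp: list[int] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 columns, found {len(fields)}"
                )
            raw_chrom.append(fields[0])
            raw_name.append(fields[1])
            raw_cm.append(float(fields[2]))
            raw_bp.append(int(fields[3]))
    n_markers = len(raw_name)

    individuals: list[str] = []
    breeds: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} markers, found {len(fields)}"
                )
            breeds.append(fields[0])
            individuals.append(fields[1])
            allele_rows.append(fields[6:])

    n_ind = len(individuals)
    calls = np.full((n_ind, n_markers), MISSING, dtype=np.int8)
    alleles = np.asarray(allele_rows, dtype=object).reshape(n_ind, n_markers, 2) if n_ind else np.empty((0, n_markers, 2), dtype=object)
    for j in range(n_markers):
        col = alleles[:, j, :] if n_ind else np.empty((0, 2), dtype=object)
        observed = sorted({a for a in col.ravel() if a != "0"})
        if len(observed) > 2:
            raise FormatError(
                f"{ped_path}: marker {raw_name[j]} has {len(observed)} alleles "
                f"({', '.join(observed)}); only biallelic markers are supported"
            )
        ref = observed[0] if observed else None
        for i in range(n_ind):
            a, b = col[i]
            if a == "0" or b == "0":
                continue
            calls[i, j] = int(a == ref) + int(b == ref)

    marker_map = MarkerMap(
        chrom=np.asarray(raw_chrom, dtype=object),
        name=np.asarray(raw_name, dtype=object),
        pos_bp=np.asarray(raw_bp, dtype=np.int64),
        pos_cm=None if all(c == 0 for c in raw_cm) else np.asarray(raw_cm, dtype=float),
    )
    marker_map, order = marker_map.canonicalize()
    marker_map.validate()
    gt = GenotypeTable(
        individuals=np.asarray(individuals, dtype=object),
        breed=np.asarray(breeds, dtype=object),
        calls=calls[:, order],
    )
    gt.validate(marker_map)
    return gt, marker_map


def write_genotypes(gt: GenotypeTable, marker_map: MarkerMap, ped_path: str, map_path: str) -> None:
    """Write a PLINK-text pair; reference allele "A", alternate "B"."""
    with open(map_path, "w") as fh:
        cm = marker_map.pos_cm if marker_map.pos_cm is not None else np.zeros(marker_map.n_markers)
        for c, n, g, p in zip(marker_map.chrom, marker_map.name, cm, marker_map.pos_bp):
            fh.write(f"{c}\t{n}\t{g:g}\t{p}\n")
    code = {2: ("A", "A"), 1: ("A", "B"), 0: ("B", "B"), MISSING: ("0", "0")}
    with open(ped_path, "w") as fh:
        for i in range(gt.n_individuals):
            row = [str(gt.breed[i]), str(gt.individuals[i]), "0", "0", "0", "-9"]
            for call in gt.calls[i]:
                row.extend(code[int(call)])
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Phased haplotype TSV

_ALLELE_TOKENS = {"0": 0, "1": 1, ".": MISSING}
_ALLELE_CHARS = {0: "0", 1: "1", MISSING: "."}


def read_haplotypes(tsv_path: str, map_path: Optional[str] = None) -> tuple[HaplotypePanel, Optional[MarkerMap]]:
    """Read the phased-haplotype TSV dialect (one row per haplotype)."""
    ids: list[str] = []
    labels: list[str] = []
    rows: list[list[int]] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("haplotype_id\tbreed"):
            raise FormatError(f"{tsv_path}:1: missing 'haplotype_id<TAB>breed' header")
        n_cols = len(header.split("\t"))
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise FormatError(
                    f"{tsv_path}:{lineno}: expected {n_cols} columns, found {len(fields)}"
                )
            ids.append(fields[0])
            labels.append(fields[1])
            try:
                rows.append([_ALLELE_TOKENS[tok] for tok in fields[2:]])
            except KeyError as exc:
                raise FormatError(
                    f"{tsv_path}:{lineno}: invalid allele token {exc.args[0]!r} "
                    "(expected 0, 1 or .)"
                ) from None
    panel = HaplotypePanel(
        haplotype_ids=np.asarray(ids, dtype=object),
        alleles=np.asarray(rows, dtype=np.int8).reshape(len(ids), n_cols - 2),
        labels=np.asarray(labels, dtype=object),
    )
    marker_map = read_map(map_path) if map_path is not None else None
    if marker_map is not None:
        panel.validate(marker_map)
    else:
        panel.validate()
    return panel, marker_map


def write_haplotypes(panel: HaplotypePanel, tsv_path: str) -> None:
    with open(tsv_path, "w") as fh:
        n = panel.n_markers
        fh.write("haplotype_id\tbreed\t" + "\t".join(f"m{j + 1}" for j in range(n)) + "\n")
        for i in range(panel.n_haplotypes):
            cells = "\t".join(_ALLELE_CHARS[int(a)] for a in panel.alleles[i])
            fh.write(f"{panel.haplotype_ids[i]}\t{panel.labels[i]}\t{cells}\n")


def diplotypes_to_panel(gt: GenotypeTable) -> None:
    raise NotImplementedError("phasing is an external step; supply phased haplotypes")


# ---------------------------------------------------------------------------
# Painting matrix TSV


def read_painting(tsv_path: str) -> AncestryPainting:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"haplotype_id": str})
    if "haplotype_id" not in df.columns:
        raise FormatError(f"{tsv_path}: missing 'haplotype_id' column")
    probs = df.drop(columns=["haplotype_id"]).to_numpy(dtype=np.float64)
    painting = AncestryPainting(
        haplotype_ids=df["haplotype_id"].to_numpy(dtype=object), prob_A=probs
    )
    painting.validate()
    return painting


def write_painting(painting: AncestryPainting, tsv_path: str, marker_names: Optional[Sequence[str]] = None) -> None:
    n = painting.n_markers
    cols = list(marker_names) if marker_names is not None else [f"m{j + 1}" for j in range(n)]
    with open(tsv_path, "w") as fh:
        fh.write("haplotype_id\t" + "\t".join(map(str, cols)) + "\n")
        for i in range(painting.n_haplotypes):
            cells = "\t".join(format_float(v) for v in painting.prob_A[i])
            fh.write(f"{painting.haplotype_ids[i]}\t{cells}\n")


# ---------------------------------------------------------------------------
# Block tables (BED5-like)

_BLOCK_HEADER = "#chrom\tstart\tend\tlabel\thaplotype_id"


def write_blocks(blocks: BlockSet, path: str) -> None:
    """Write a BlockSet as a BED5-like table; invariants are checked first."""
    blocks.validate()
    with open(path, "w") as fh:
        fh.write(_BLOCK_HEADER + "\n")
        for chrom in sorted(blocks.span_bp, key=chrom_sort_key):
            lo, hi = blocks.span_bp[chrom]
            fh.write(f"#span\t{chrom}\t{lo}\t{hi}\n")
        for b in blocks.sorted_blocks():
            fh.write(f"{b.chrom}\t{b.start_bp}\t{b.end_bp}\t{b.label}\t{b.haplotype_id}\n")


def read_blocks(path: str) -> BlockSet:
    blocks = BlockSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#span\t"):
                _, chrom, lo, hi = line.split("\t")
                blocks.span_bp[chrom] = (int(lo), int(hi))
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, found {len(fields)}")
            chrom, start, end, label, hid = fields
            blocks.blocks.append(Block(hid, chrom, int(start), int(end), label))
    blocks.validate()
    return blocks


# ---------------------------------------------------------------------------
# Result tables


def format_float(value: float) -> str:
    """Serialize a float at 6 significant digits ('%.6g')."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.6g}"


def write_table(rows: Iterable[Mapping], path: str, sort_by: Optional[str] = None) -> None:
    """Write homogeneous records as a TSV sorted by its primary key.

    The primary key defaults to the first column. Floats are serialized at
    6 significant digits; None/NaN becomes "NA".
    """
    rows = list(rows)
    if rows:
        columns = list(rows[0].keys())
        key = sort_by if sort_by is not None else columns[0]
        rows.sort(key=lambda r: r[key])
    else:
        columns = []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            cells = []
            for c in columns:
                v = r[c]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    cells.append("NA")
                elif isinstance(v, (float, np.floating)):
                    cells.append(format_float(float(v)))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# ---------------------------------------------------------------------------
# Config


def read_config(path: str) -> dict:
    """Read a flat YAML key:value config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a flat key:value mapping")
    return data


def write_config(config: Mapping, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, default_flow_style=False, sort_keys=True)
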