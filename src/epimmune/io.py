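"""Plain-text readers and writers for the pipeline's file formats.

Formats: β matrix CSV (probe × sample), counts TSV (gene, length, samples),
probe annotation TSV, GMT gene-set files, sample sheet CSV, clinical CSV,
IHC CSV, cell-type reference TSV, and result TSV/BED/JSON writers. DMR
coordinates are 1-based closed internally; the BED writer converts to
0-based half-open at the boundary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .containers import BetaMatrix, CellTypeReference, CountMatrix

__all__ = [
    "read_beta",
    "write_beta",
    "read_annotation",
    "write_annotation",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_sample_sheet",
    "read_clinical",
    "read_ihc",
    "read_reference",
    "write_reference",
    "write_dmrs_bed",
    "sha256_of",
]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def read_beta(beta_path, annotation_path) -> BetaMatrix:
    values = pd.read_csv(beta_path, index_col=0)
    annotation = read_annotation(annotation_path)
    return BetaMatrix(values, annotation)


def write_beta(beta: BetaMatrix | pd.DataFrame, path) -> None:
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    values.to_csv(path, index_label="probe_id")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("snp_flag", "multimap_flag"):
        if col in ann.columns:
            ann[col] = ann[col].astype(bool)
    for col in ann.columns:
        if col.startswith("beads_ok_"):
            ann[col] = ann[col].astype(bool)
    return ann


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="probe_id")


def read_counts(path, lengths_path=None) -> CountMatrix:
    """Read a counts TSV. Gene lengths come from a ``length`` column in the
    counts file itself or from a separate two-column TSV (gene, length)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    elif "length" in df.columns:
        lengths = df.pop("length")
    else:
        raise ValueError("no 'length' column in counts file and no lengths_path given")
    return CountMatrix(df.astype(int), lengths.astype(float))


def write_counts(counts: CountMatrix, path) -> None:
    out = counts.counts.copy()
    out.insert(0, "length", counts.lengths.astype(int))
    out.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> dict:
    """Read a GMT file: one set per line, tab-separated
    name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict, path, description: str = "epimmune") -> None:
    lines = []
    for name, genes in sets.items():
        lines.append("\t".join([name, description, *map(str, genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    need = {"sample_id", "participant_id", "timepoint", "dose"}
    missing = need - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    bad_tp = set(sheet["timepoint"]) - {"baseline", "on_treatment"}
    if bad_tp:
        raise ValueError(f"unknown timepoints {sorted(bad_tp)}")
    return sheet


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")


def read_ihc(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_reference(path) -> CellTypeReference:
    return CellTypeReference(pd.read_csv(path, sep="\t", index_col=0))


def write_reference(reference: CellTypeReference, path) -> None:
    reference.profiles.to_csv(path, sep="\t", index_label="probe_id")


def write_dmrs_bed(dmr_table: pd.DataFrame, path) -> None:
    """Write DMRs as BED: chrom, start−1, end (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in dmr_table.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"dmr_p{row['p_adjusted']:.4g}\n"
            )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
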