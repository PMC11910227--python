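"""Core in-memory containers for the paired-biopsy multi-omic pipeline.

The substrate objects are thin, validated wrappers around pandas frames:

* :class:`BetaMatrix` — CpG probe × sample methylation proportions (β), with
  the probe annotation (genomic position, gene, promoter region class, QC
  flags) attached.
* :class:`CountMatrix` — gene × sample integer read counts plus gene lengths,
  the hand-off point downstream of alignment/counting.
* :class:`PairedDesign` — the baseline / on-treatment pairing of samples
  within participants that every differential analysis here is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Probe region classes counted as "promoter" throughout the package.
PROMOTER_REGIONS = ("TSS200", "5UTR")

#: Columns every probe annotation table must carry.
ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "gene",
    "region",
    "cytoband",
    "snp_flag",
    "multimap_flag",
)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} IDs: {dupes}")


@dataclass
class BetaMatrix:
    """Probe × sample methylation proportions with probe annotation.

    Parameters
    ----------
    values : DataFrame
        β values in [0, 1]; rows indexed by probe ID, columns by sample ID.
    annotation : DataFrame
        One row per probe (indexed by probe ID) with at least
        :data:`ANNOTATION_COLUMNS`. Optional per-sample QC columns
        ``detection_p_<sample>`` and ``beads_ok_<sample>`` feed probe QC.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        missing = self.values.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} probes lack annotation rows (e.g. {missing[:3].tolist()})"
            )
        lacking = [c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns]
        if lacking:
            raise ValueError(f"annotation missing columns: {lacking}")
        # keep annotation aligned and restricted to the probes present
        self.annotation = self.annotation.loc[self.values.index]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probes) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[probes], self.annotation.loc[probes])

    def promoter_mask(self, regions=PROMOTER_REGIONS) -> pd.Series:
        return self.annotation["region"].isin(regions)


@dataclass
class CountMatrix:
    """Gene × sample non-negative integer counts with gene lengths (bp)."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.counts.index[self.lengths.isna()][:3].tolist()
            raise ValueError(f"gene lengths missing for {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class PairedDesign:
    """Ordered (participant, baseline sample, on-treatment sample) triples."""

    pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        seen: set = set()
        for part, base, on in self.pairs:
            for s in (base, on):
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one pair")
                seen.add(s)

    @classmethod
    def from_sample_sheet(cls, sheet: pd.DataFrame) -> "PairedDesign":
        """Build from a sample sheet with columns
        sample_id, participant_id, timepoint ∈ {baseline, on_treatment}."""
        pairs = []
        for part, grp in sheet.groupby("participant_id", sort=True):
            tp = grp.set_index("timepoint")["sample_id"]
            if "baseline" not in tp.index or "on_treatment" not in tp.index:
                raise ValueError(f"participant {part!r} lacks a complete baseline/on_treatment pair")
            pairs.append((part, tp["baseline"], tp["on_treatment"]))
        return cls(pairs)

    @property
    def participants(self) -> list:
        return [p for p, _, _ in self.pairs]

    @property
    def baseline_samples(self) -> list:
        return [b for _, b, _ in self.pairs]

    @property
    def on_treatment_samples(self) -> list:
        return [o for _, _, o in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CellTypeReference:
    """Signature-probe × cell-type mean β profiles for deconvolution."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.profiles.index, "probe")
        _check_unique(self.profiles.columns, "cell type")
        if self.profiles.shape[1] < 2:
            raise ValueError("reference needs at least 2 cell types")
        arr = self.profiles.to_numpy(dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("reference β values must lie in [0, 1]")

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.columns

    @property
    def probe_ids(self) -> pd.Index:
        return self.profiles.index
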