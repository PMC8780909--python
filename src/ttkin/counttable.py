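"""Gene x sample count table with sample metadata and spike-in flags.

The pipeline's entry point: integer counts for raw sequencing data,
real-valued after normalization.  Samples are annotated with a condition
(e.g. WT / KO), an assay (``nascent`` = 4SU-labeled TT-seq library,
``total`` = total RNA library) and a replicate index.  Exogenous spike-in
RNAs (the Drosophila S2 role) are flagged per gene so normalization can
restrict itself to them.

On disk the table is two TSV files: a counts matrix (``gene_id``,
``spikein``, one column per sample) and a sample sheet (``sample_id``,
``condition``, ``assay``, ``replicate``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

VALID_ASSAYS = ("total", "nascent")

SAMPLE_SHEET_COLUMNS = ("condition", "assay", "replicate")


@dataclass
class CountTable:
    """Counts (genes x samples) + sample sheet + per-gene spike-in flags.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id, one column per sample_id.  Integer for
        raw data; real-valued tables (post-normalization) are accepted.
    samples
        DataFrame indexed by sample_id with columns ``condition``, ``assay``
        (``nascent`` or ``total``) and ``replicate`` (int).
    spikein
        Boolean Series indexed like ``counts``; True marks spike-in genes.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    spikein: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.samples = self.samples.copy()
        self.spikein = self.spikein.reindex(self.counts.index)
        if self.spikein.isna().any():
            raise ValidationError("spikein flags missing for some genes")
        self.spikein = self.spikein.astype(bool)
        if list(self.samples.index) != list(self.counts.columns):
            raise ValidationError(
                "sample sheet rows must match count columns (same ids, same order)"
            )
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample sheet lacks columns: {missing}")
        bad = set(self.samples["assay"]) - set(VALID_ASSAYS)
        if bad:
            raise ValidationError(f"unknown assay labels: {sorted(bad)}")
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValidationError("counts contain non-finite values")
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")

    # -- selection ---------------------------------------------------------

    def sample_ids(self, condition: str | None = None, assay: str | None = None) -> list[str]:
        """Sample ids matching the given condition and/or assay."""
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if assay is not None:
            mask &= self.samples["assay"] == assay
        return list(self.samples.index[mask])

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "spikein", self.spikein.astype(bool))
        out.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountTable":
        raw = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        if "spikein" not in raw.columns:
            raise ValidationError(f"{counts_path}: no 'spikein' column")
        flags = raw["spikein"].astype(str).str.lower().isin(("true", "1"))
        counts = raw.drop(columns=["spikein"])
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(counts=counts, samples=samples, spikein=flags)


def make_sample_sheet(
    conditions: list[str], assays: list[str], n_replicates: int
) -> pd.DataFrame:
    """Build a fully crossed condition x assay x replicate sample sheet."""
    rows = []
    for cond in conditions:
        for assay in assays:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_{assay}_rep{rep}",
                        "condition": cond,
                        "assay": assay,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")
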