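"""Gene-level RNA-seq quantification: counts, size factors, FPKM, ratios.

Fragments (proper pairs, counted once via the leftmost mate) are assigned
to the gene containing the fragment midpoint — simple and unambiguous in
operon-dense bacterial genomes.  Libraries are normalized with
median-of-ratios size factors (the DESeq2 scheme): each sample's factor is
the median, over genes with all-positive counts, of that sample's count
divided by the gene's geometric mean across samples.

FPKM is fragments per kilobase of annotated gene length per million
assigned fragments.  For deletion strains, genes are annotated with their
wildtype length, so FPKM of partially deleted genes is deliberately an
underestimate (reads can only come from the retained segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import fragments_from_sam, read_sam


@dataclass
class ExpressionTable:
    """Gene × sample counts with metadata, size factors, and FPKM."""

    counts: pd.DataFrame  # genes × samples, integer fragment counts
    meta: pd.DataFrame  # one row per sample: genotype, timepoint, replicate, batch
    annotation: pd.DataFrame  # gene_id, length, operon_id, regulon
    size_factors: pd.Series = field(default=None)
    fpkm: pd.DataFrame = field(default=None)
    unassigned: pd.Series = field(default=None)
    #: genes annotated (i.e. physically present) per genotype; None = all
    presence: Optional[dict[str, set]] = None

    def genes_present(self, genotype: str) -> set:
        if self.presence is None:
            return set(self.counts.index)
        return self.presence[genotype]

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not computed")
        return self.counts.div(self.size_factors, axis=1)

    def condition(self, genotype: str, timepoint: int) -> list[str]:
        m = self.meta
        sel = m[(m["genotype"] == genotype) & (m["timepoint"] == timepoint)]
        return list(sel.index)


def count_fragments(
    fragments: Iterable[tuple[str, int, int]],
    annotation: pd.DataFrame,
    reference_id: str,
) -> tuple[pd.Series, int]:
    """Midpoint-assign fragments to genes.

    ``fragments`` yields (reference_name, start, insert_length) per proper
    pair.  Returns (per-gene counts, unassigned count).  A fragment whose
    reference is not ``reference_id`` is an error: counting against the
    wrong annotation space would silently corrupt the matrix.
    """
    ann = annotation.sort_values("start").reset_index(drop=True)
    starts = ann["start"].to_numpy()
    ends = ann["end"].to_numpy()
    gene_ids = ann["gene_id"].to_numpy()
    counts = np.zeros(len(ann), dtype=np.int64)
    unassigned = 0
    mids = []
    for ref, start, tlen in fragments:
        if ref != reference_id:
            raise ValueError(f"alignment reference {ref!r} not in annotation space {reference_id!r}")
        mids.append(start + tlen // 2)
    mid = np.asarray(mids, dtype=np.int64)
    if mid.size:
        idx = np.searchsorted(starts, mid, side="right") - 1
        ok = (idx >= 0) & (mid < ends[np.clip(idx, 0, None)])
        np.add.at(counts, idx[ok], 1)
        unassigned = int((~ok).sum())
    return pd.Series(counts, index=pd.Index(gene_ids, name="gene_id")), unassigned


def count_sam(path: str | Path, annotation: pd.DataFrame, reference_id: str) -> tuple[pd.Series, int]:
    return count_fragments(fragments_from_sam(read_sam(path)), annotation, reference_id)


def size_factors(counts: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Median-of-ratios size factors.

    Returns (factors, per-gene geometric means of the reference
    pseudo-sample).  Genes with a zero count in any sample are excluded
    from the median.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    positive = counts.gt(0).all(axis=1)
    if not positive.any():
        raise ValueError("cannot normalize: no gene with positive counts in every sample")
    log_counts = np.log(counts[positive].astype(float))
    log_geomean = log_counts.mean(axis=1)
    factors = np.exp(log_counts.sub(log_geomean, axis=0).median(axis=0))
    geomeans = np.exp(log_geomean).reindex(counts.index)
    factors.name = "size_factor"
    return factors, geomeans


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million assigned fragments.

    ``totals`` defaults to the column sums of ``counts`` (total assigned
    fragments per sample).
    """
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0) if totals is None else totals
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"zero assigned fragments in sample(s) {bad}")
    return counts.div(lengths, axis=0).div(totals, axis=1) * 1e9


def quantify_experiment(
    manifest: pd.DataFrame,
    model=None,
    background=None,
    annotations: Optional[dict[str, pd.DataFrame]] = None,
) -> ExpressionTable:
    """Count every library in a manifest and assemble an ExpressionTable.

    Annotations are per-genotype (each strain's reads are mapped to its own
    reference).  When not supplied they are derived from the packaged
    operon model and background gene set.
    """
    from .simulate import build_strain_transcriptome, load_background

    if annotations is None:
        from .reference import load_reference

        model = model if model is not None else load_reference()
        background = background if background is not None else load_background()
        annotations = {}
        for genotype in manifest["genotype"].unique():
            annotations[genotype] = build_strain_transcriptome(model, genotype, background).annotation

    col_counts: dict[str, pd.Series] = {}
    unassigned: dict[str, int] = {}
    meta_rows = []
    for _, row in manifest.iterrows():
        ann = annotations[row["genotype"]]
        counts, un = count_sam(row["sam"], ann, row["reference_id"])
        col_counts[row["library_id"]] = counts
        unassigned[row["library_id"]] = un
        meta_rows.append(
            {
                "library_id": row["library_id"],
                "genotype": row["genotype"],
                "timepoint": int(row["timepoint"]),
                "replicate": int(row.get("replicate", 1)),
                "batch": row.get("batch", "batch1"),
            }
        )
    counts = pd.DataFrame(col_counts).fillna(0).astype(int)
    counts.index.name = "gene_id"
    meta = pd.DataFrame(meta_rows).set_index("library_id")

    # one annotation row per gene (wildtype lengths take precedence)
    ann_all = (
        pd.concat(annotations.values())
        .drop_duplicates(subset="gene_id", keep="first")
        .set_index("gene_id")[["length", "operon_id", "regulon"]]
    )
    ann_all = ann_all.reindex(counts.index)

    factors, _ = size_factors(counts)
    table = ExpressionTable(
        counts=counts,
        meta=meta,
        annotation=ann_all,
        size_factors=factors,
        unassigned=pd.Series(unassigned),
        presence={g: set(a["gene_id"]) for g, a in annotations.items()},
    )
    table.fpkm = fpkm(counts, ann_all["length"])
    return table


def fold_change_table(
    expr: ExpressionTable,
    baseline: tuple[str, int],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 ratios of replicate-mean normalized counts vs baseline.

    The pseudocount (default 1 normalized count) keeps zero-count genes
    finite on the log scale.
    """
    base_samples = expr.condition(*baseline)
    if not base_samples:
        raise ValueError(f"no samples for baseline {baseline}")
    norm = expr.normalized()
    base_mean = norm[base_samples].mean(axis=1)
    rows = []
    for (genotype, timepoint), grp in expr.meta.groupby(["genotype", "timepoint"]):
        mean = norm[list(grp.index)].mean(axis=1)
        log2fc = np.log2((mean + pseudocount) / (base_mean + pseudocount))
        for gene_id, value in log2fc.items():
            rows.append(
                {
                    "gene_id": gene_id,
                    "genotype": genotype,
                    "timepoint": timepoint,
                    "log2_ratio": float(value),
                    "baseline_mean": float(base_mean[gene_id]),
                    "regulon": expr.annotation.loc[gene_id, "regulon"],
                }
            )
    return pd.DataFrame(rows)


def operon_relative_levels(
    expr: ExpressionTable,
    reference_genotype: str = "wildtype",
) -> pd.DataFrame:
    """Per-operon mean-FPKM ratios vs the reference genotype at matched
    timepoints, with standard errors propagated from replicate means.

    The operon level averages only member genes physically present in the
    strain: a gene excised by the strain's construct is not a biological
    zero and must not dilute the operon mean.
    """

    def cond_stats(samples: list[str], genotype: str) -> tuple[pd.Series, pd.Series]:
        present = expr.genes_present(genotype)
        keep = expr.fpkm.index.isin(present)
        sub = expr.fpkm.loc[keep, samples].groupby(expr.annotation.loc[keep, "operon_id"]).mean()
        sub = sub.reindex(sorted(expr.annotation["operon_id"].dropna().unique()))
        mean = sub.mean(axis=1)
        se = sub.std(axis=1, ddof=1) / np.sqrt(sub.shape[1]) if sub.shape[1] > 1 else pd.Series(
            np.nan, index=sub.index
        )
        return mean, se

    operon_ids = sorted(expr.annotation["operon_id"].dropna().unique())
    rows = []
    conditions = expr.meta.groupby(["genotype", "timepoint"]).groups
    for (genotype, timepoint), samples in conditions.items():
        ref_samples = expr.condition(reference_genotype, timepoint)
        if len(ref_samples) < 2 or len(samples) < 2:
            raise ValueError("need ≥ 2 replicates per condition for operon ratios")
        mean, se = cond_stats(list(samples), genotype)
        ref_mean, ref_se = cond_stats(ref_samples, reference_genotype)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = mean / ref_mean
            rel_se = np.sqrt((se / mean) ** 2 + (ref_se / ref_mean) ** 2)
            ratio_se = np.abs(ratio) * rel_se
        for operon in operon_ids:
            r = ratio[operon]
            rows.append(
                {
                    "operon_id": operon,
                    "genotype": genotype,
                    "timepoint": timepoint,
                    "level": float(mean[operon]),
                    "level_se": float(se[operon]),
                    "ratio_vs_reference": float(r) if np.isfinite(r) else np.nan,
                    "ratio_se": float(ratio_se[operon]) if np.isfinite(r) else np.nan,
                }
            )
    return pd.DataFrame(rows)
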