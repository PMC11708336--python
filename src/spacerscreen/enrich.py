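"""Screen enrichment: spacer frequencies, post/pre enrichment ratios,
region/strand annotation, group statistics, and enrichment-vs-expression
correlation.

Frequencies are computed over the spacers extracted in each sample; the
enrichment ratio of a spacer is its frequency at a post-infection timepoint
divided by its frequency in the uninfected (t0) library.  Spacers absent at
t0 get NA under the default zero policy, or a shared pseudocount under the
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extract import CountTable
from .genome import UNTRANSCRIBED, GenomeAnnotation, SpacerRecord, is_targeting, region_of
from .rnaseq import CoverageProfile
from .stats import WelchResult, pearson_r, welch_t_test


def compute_frequencies(table: CountTable) -> dict[str, float]:
    """Per-spacer frequency ``count / total_extracted``; sums to 1."""
    total = sum(table.counts.values())
    if total == 0:
        raise ValueError(f"count table {table.sample_id!r} is empty")
    return {s: c / total for s, c in table.counts.items()}


def compute_enrichment(
    post: CountTable,
    pre: CountTable,
    zero_policy: str = "na",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Enrichment table over the union of spacers in ``pre`` and ``post``.

    ``zero_policy="na"``: E = f_post / f_pre, NA where f_pre = 0.
    ``zero_policy="pseudocount"``: frequencies use (c + a) / (total + a*U)
    where U is the union library size and ``a`` the pseudocount.
    """
    union = sorted(set(pre.counts) | set(post.counts))
    c_pre = np.array([pre.counts.get(s, 0) for s in union], dtype=float)
    c_post = np.array([post.counts.get(s, 0) for s in union], dtype=float)
    if zero_policy == "na":
        f_pre = c_pre / c_pre.sum()
        f_post = c_post / c_post.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = np.where(c_pre > 0, f_post / np.where(c_pre > 0, f_pre, 1.0), np.nan)
    elif zero_policy == "pseudocount":
        a = pseudocount
        u = len(union)
        f_pre = (c_pre + a) / (c_pre.sum() + a * u)
        f_post = (c_post + a) / (c_post.sum() + a * u)
        enr = f_post / f_pre
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return pd.DataFrame(
        {
            "spacer_seq": union,
            "count_pre": c_pre.astype(int),
            "count_post": c_post.astype(int),
            "f_pre": f_pre,
            "f_post": f_post,
            "enrichment": enr,
        }
    )


def annotate_enrichment(
    enr: pd.DataFrame,
    manifest: Sequence[SpacerRecord],
    genome: GenomeAnnotation,
) -> pd.DataFrame:
    """Attach region label, strand, targeting flag, and genome position.

    Spacers absent from the manifest (or flagged as duplicates, which cannot
    be placed unambiguously) are labelled ``unmapped``.
    """
    by_seq: dict[str, SpacerRecord] = {}
    for rec in manifest:
        if not rec.duplicate:
            by_seq.setdefault(rec.sequence, rec)
    regions, strands, targeting, starts = [], [], [], []
    for seq in enr["spacer_seq"]:
        rec = by_seq.get(seq)
        if rec is None or rec.source != genome.name:
            regions.append("unmapped")
            strands.append(".")
            targeting.append(False)
            starts.append(-1)
        else:
            regions.append(region_of(rec, genome))
            strands.append(rec.strand)
            targeting.append(is_targeting(rec, genome))
            starts.append(rec.start)
    out = enr.copy()
    out["region"] = regions
    out["strand"] = strands
    out["targeting"] = targeting
    out["start"] = starts
    return out


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


def group_stats(enr: pd.DataFrame, group_col: str = "region") -> pd.DataFrame:
    """Mean/SD of non-NA enrichment per group (natural scale)."""
    df = enr.dropna(subset=["enrichment"])
    rows = []
    for label, sub in df.groupby(group_col, sort=True):
        vals = sub["enrichment"].to_numpy()
        rows.append(
            {
                "group": label,
                "n": len(vals),
                "mean_enrichment": float(np.mean(vals)),
                "sd_enrichment": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(
    enr: pd.DataFrame,
    group_a: dict[str, object],
    group_b: dict[str, object],
    label_a: str = "A",
    label_b: str = "B",
    log_scale: bool = False,
) -> tuple[GroupSummary, GroupSummary, WelchResult]:
    """Mean/SD for two named groups plus Welch's t-test between them.

    Groups are selected by column->value filters, e.g.
    ``{"region": "PE", "targeting": True}``.  Statistics are on the natural
    enrichment scale unless ``log_scale``.
    """
    def select(filters: dict[str, object]) -> np.ndarray:
        mask = enr["enrichment"].notna()
        for col, val in filters.items():
            mask &= enr[col] == val
        vals = enr.loc[mask, "enrichment"].to_numpy(dtype=float)
        return np.log(vals) if log_scale else vals

    a, b = select(group_a), select(group_b)
    summaries = []
    for label, vals in ((label_a, a), (label_b, b)):
        summaries.append(
            GroupSummary(
                label=label,
                n=len(vals),
                mean=float(np.mean(vals)) if len(vals) else np.nan,
                sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            )
        )
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2 for the Welch test")
    return summaries[0], summaries[1], welch_t_test(a, b)


def correlate_with_expression(
    enr: pd.DataFrame,
    coverage: CoverageProfile,
    timepoint: float,
    manifest: Sequence[SpacerRecord],
    genome: GenomeAnnotation,
) -> tuple[float, int]:
    """Pearson r between spacer enrichment and target transcript coverage.

    Each spacer's expression is the mean per-position normalized coverage
    over its target interval on the mRNA strand (the strand opposite the
    spacer).  Only spacers with non-NA enrichment and a unique placement on
    ``genome`` enter the correlation; returns ``(r, n)``.
    """
    norm = coverage.normalized()
    by_seq = {rec.sequence: rec for rec in manifest if not rec.duplicate}
    xs, ys = [], []
    for seq, e in zip(enr["spacer_seq"], enr["enrichment"]):
        if not np.isfinite(e):
            continue
        rec = by_seq.get(seq)
        if rec is None or rec.source != genome.name:
            continue
        mrna_strand = "-" if rec.strand == "+" else "+"
        track = norm.values[timepoint][mrna_strand]
        xs.append(float(np.mean(track[rec.start : rec.end])))
        ys.append(float(e))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} spacers usable for correlation; need >= 3")
    return pearson_r(xs, ys), len(xs)


def write_enrichment_tsv(enr: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        enr.to_csv(fh, sep="\t", index=False)
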