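"""Annotation tables and group-level statistics.

Joins rankings to per-protein annotations (best-hit BLAST bit scores,
protein lengths, pathway labels, subcellular location flags) and computes
the table-style summaries: category fractions with two denominators,
conservation group means with one-way ANOVA and Duncan's multiple-range
compact letter display, location cross-tabs, and the top/bottom ratio
goodness-of-fit chi-square.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from prorank.network_io import EdgeTableFormatError, _open_lines
from prorank.ranking_analysis import RankGroups

logger = logging.getLogger(__name__)

LOCATION_FLAGS = ("nucleus", "cytoplasm", "membrane")

ANNOTATION_COLUMNS = (
    "protein_id",
    "blast_bits",
    "evalue",
    "length_aa",
    "pathway_labels",
    "nucleus",
    "cytoplasm",
    "membrane",
)

BLAST_TABULAR_NCOL = 12  # outfmt-6: qseqid..bitscore


@dataclass(frozen=True)
class AnnotationTable:
    """Per-protein annotations keyed by protein identifier.

    ``blast_bits`` / ``evalue`` are NaN for proteins without a BLAST hit;
    such proteins are excluded (not zero-filled) from conservation
    summaries. Location flags are independent booleans — a protein may
    carry several.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS[1:] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"annotation table missing column(s): {missing}")
        bits = self.frame["blast_bits"]
        if (bits.dropna() < 0).any():
            raise ValueError("blast_bits must be >= 0")
        if (self.frame["length_aa"] < 1).any():
            raise ValueError("length_aa must be >= 1")

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, object]]) -> "AnnotationTable":
        frame = pd.DataFrame(list(records))
        frame = frame.set_index("protein_id", drop=False).sort_index()
        frame["pathway_labels"] = frame["pathway_labels"].apply(
            lambda v: frozenset(v) if not isinstance(v, frozenset) else v
        )
        for flag in LOCATION_FLAGS:
            frame[flag] = frame[flag].astype(bool)
        return cls(frame=frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, protein: str) -> bool:
        return protein in self.frame.index

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def has_hit(self, protein: str) -> bool:
        return protein in self and not math.isnan(self.frame.at[protein, "blast_bits"])

    def bits(self, protein: str) -> float:
        return float(self.frame.at[protein, "blast_bits"])

    def length(self, protein: str) -> int:
        return int(self.frame.at[protein, "length_aa"])

    def labels(self, protein: str) -> frozenset[str]:
        if protein not in self:
            return frozenset()
        return self.frame.at[protein, "pathway_labels"]

    def location(self, protein: str, flag: str) -> bool:
        return bool(self.frame.at[protein, flag])


def read_annotation_table(stream: str | IO[str]) -> AnnotationTable:
    """Read the annotation TSV dialect.

    Columns: protein_id, blast_bits, evalue, length_aa, pathway_labels
    (semicolon-separated), nucleus, cytoplasm, membrane (0/1). Empty or
    ``NA`` bits/evalue mean "no BLAST hit".
    """
    records = []
    header_seen = False
    for lineno, line in _open_lines(stream):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip().lower() for f in fields[: len(ANNOTATION_COLUMNS)]] != list(
                ANNOTATION_COLUMNS
            ):
                raise EdgeTableFormatError(
                    f"line {lineno}: expected annotation header {ANNOTATION_COLUMNS}"
                )
            header_seen = True
            continue
        if len(fields) < len(ANNOTATION_COLUMNS):
            raise EdgeTableFormatError(
                f"line {lineno}: expected {len(ANNOTATION_COLUMNS)} fields"
            )

        def _num(s: str) -> float:
            s = s.strip()
            return float("nan") if s in ("", "NA", "nan") else float(s)

        labels = frozenset(
            lab for lab in fields[4].strip().split(";") if lab
        )
        records.append(
            {
                "protein_id": fields[0].strip(),
                "blast_bits": _num(fields[1]),
                "evalue": _num(fields[2]),
                "length_aa": int(fields[3]),
                "pathway_labels": labels,
                "nucleus": fields[5].strip() == "1",
                "cytoplasm": fields[6].strip() == "1",
                "membrane": fields[7].strip() == "1",
            }
        )
    if not records:
        raise EdgeTableFormatError("annotation table has no data rows")
    return AnnotationTable.from_records(records)


def write_annotation_table(table: AnnotationTable, stream: str | IO[str]) -> None:
    if isinstance(stream, str):
        with open(stream, "w", encoding="utf-8", newline="\n") as handle:
            write_annotation_table(table, handle)
        return
    stream.write("\t".join(ANNOTATION_COLUMNS) + "\n")
    for protein in table.proteins:
        row = table.frame.loc[protein]
        bits = "NA" if math.isnan(row["blast_bits"]) else f"{row['blast_bits']:.17g}"
        evalue = "NA" if math.isnan(row["evalue"]) else f"{row['evalue']:.6g}"
        labels = ";".join(sorted(row["pathway_labels"]))
        flags = "\t".join("1" if row[f] else "0" for f in LOCATION_FLAGS)
        stream.write(
            f"{protein}\t{bits}\t{evalue}\t{int(row['length_aa'])}\t{labels}\t{flags}\n"
        )


def read_blast_tabular(stream: str | IO[str]) -> dict[str, tuple[float, float]]:
    """Best-hit (bit score, e-value) per query from 12-column BLAST tabular.

    For each query only the hit with the maximal bit score is kept. Queries
    absent from the file simply do not appear in the map ("no hit"). An
    empty file yields an empty map.
    """
    best: dict[str, tuple[float, float]] = {}
    for lineno, line in _open_lines(stream):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != BLAST_TABULAR_NCOL:
            raise EdgeTableFormatError(
                f"line {lineno}: expected {BLAST_TABULAR_NCOL} tab-separated "
                f"columns (outfmt 6), got {len(fields)}"
            )
        query = fields[0]
        try:
            evalue = float(fields[10])
            bits = float(fields[11])
        except ValueError as exc:
            raise EdgeTableFormatError(
                f"line {lineno}: unparseable evalue/bitscore"
            ) from exc
        if query not in best or bits > best[query][0]:
            best[query] = (bits, evalue)
    return best


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Returns the F statistic and upper-tail p from the F distribution with
    (g−1, N−g) degrees of freedom. Zero within-group variance with unequal
    means yields (inf, 0.0).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    grand = np.concatenate(arrays)
    grand_mean = grand.mean()
    ss_between = sum(len(a) * (a.mean() - grand_mean) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = len(grand) - len(arrays)
    ms_between = ss_between / df_between
    if ss_within == 0.0:
        if ms_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f_stat = ms_between / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


@lru_cache(maxsize=4096)
def _duncan_critical_q(protection: float, span: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level."""
    return float(stats.studentized_range.ppf(protection, span, df))


def duncan_mrt(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> list[str]:
    """Duncan's multiple-range test, returned as a compact letter display.

    Group means are ordered descending; each span of ``p`` consecutive
    means is compared against the critical range
    ``R_p = q(1 − α_p, p, df_err) · sqrt(MSE / n_h)`` with the protection
    level ``α_p = 1 − (1 − α)^(p−1)`` and ``n_h`` the harmonic mean group
    size. Spans are tested largest first; a span whose range falls below
    its critical range is declared homogeneous together with everything it
    contains. Groups covered by a common homogeneous span share a letter.
    Returned letter strings follow the input group order.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("Duncan's test needs every group size >= 2 (no MSE otherwise)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    g = len(arrays)
    sizes = np.array([len(a) for a in arrays])
    df_err = int(sizes.sum()) - g
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_err
    n_h = g / (1.0 / sizes).sum()
    means = np.array([a.mean() for a in arrays])
    order = np.argsort(-means, kind="stable")  # descending
    sorted_means = means[order]

    # Step-down over spans; accepted = homogeneous intervals on sorted order.
    accepted: list[tuple[int, int]] = []

    def covered(a: int, b: int) -> bool:
        return any(c <= a and b <= d for c, d in accepted)

    for span in range(g, 1, -1):
        for start in range(0, g - span + 1):
            end = start + span - 1
            if covered(start, end):
                continue
            rng = sorted_means[start] - sorted_means[end]
            if mse == 0.0:
                critical = 0.0
            else:
                protection = (1.0 - alpha) ** (span - 1)
                q = _duncan_critical_q(protection, span, df_err)
                critical = q * math.sqrt(mse / n_h)
            if rng <= critical:
                accepted.append((start, end))

    # Maximal homogeneous intervals + singletons for uncovered positions.
    maximal = [
        (a, b)
        for a, b in accepted
        if not any((c, d) != (a, b) and c <= a and b <= d for c, d in accepted)
    ]
    for pos in range(g):
        if not any(a <= pos <= b for a, b in maximal):
            maximal.append((pos, pos))
    maximal.sort()

    letters_sorted = ["" for _ in range(g)]
    for letter_idx, (a, b) in enumerate(maximal):
        letter = chr(ord("A") + letter_idx)
        for pos in range(a, b + 1):
            letters_sorted[pos] += letter

    letters = ["" for _ in range(g)]
    for sorted_pos, orig_idx in enumerate(order):
        letters[orig_idx] = letters_sorted[sorted_pos]
    return letters


@dataclass(frozen=True)
class VariableSummary:
    """Per-group means of one annotation variable, with ANOVA and letters."""

    means: dict[str, float]
    anova_F: float
    anova_p: float
    letters: dict[str, str]


@dataclass(frozen=True)
class GroupSummary:
    """Conservation summary over top/mid/bottom groups of one ranking."""

    method: str
    n_members: dict[str, int]
    n_used: dict[str, int]
    n_excluded: dict[str, int]
    bits: VariableSummary
    length: VariableSummary


def group_conservation_summary(
    groups: RankGroups,
    ann: AnnotationTable,
    method: str = "",
    min_coverage: float = 0.8,
) -> GroupSummary:
    """Mean bit score and length per rank group, with ANOVA + Duncan letters.

    Proteins without a BLAST hit are excluded from the bit-score variable
    (with the exclusion count reported, mirroring group sizes dropping from
    50 to 49); lengths use all annotated members. Raises when fewer than
    ``min_coverage`` of a group's members are annotated, or when a group is
    empty after exclusions.
    """
    named = groups.as_dict()
    bits_samples: dict[str, list[float]] = {}
    length_samples: dict[str, list[float]] = {}
    n_members: dict[str, int] = {}
    n_excluded: dict[str, int] = {}
    for name, members in named.items():
        n_members[name] = len(members)
        annotated = [p for p in members if p in ann]
        if len(annotated) < min_coverage * len(members):
            missing = sorted(set(members) - set(annotated))
            raise ValueError(
                f"group {name!r}: only {len(annotated)}/{len(members)} members "
                f"annotated (< {min_coverage:.0%}); missing: {missing[:10]}"
            )
        with_hit = [p for p in annotated if ann.has_hit(p)]
        n_excluded[name] = len(members) - len(with_hit)
        if n_excluded[name]:
            logger.info(
                "group %s: excluded %d member(s) without BLAST hit",
                name,
                n_excluded[name],
            )
        if not with_hit:
            raise ValueError(f"group {name!r} empty after BLAST-hit exclusions")
        bits_samples[name] = [ann.bits(p) for p in with_hit]
        length_samples[name] = [float(ann.length(p)) for p in annotated]

    names = list(named)

    def summarize(samples: dict[str, list[float]]) -> VariableSummary:
        data = [samples[name] for name in names]
        f_stat, p = anova_oneway(data)
        letters = duncan_mrt(data)
        return VariableSummary(
            means={name: float(np.mean(samples[name])) for name in names},
            anova_F=f_stat,
            anova_p=p,
            letters=dict(zip(names, letters)),
        )

    return GroupSummary(
        method=method,
        n_members=n_members,
        n_used={name: len(bits_samples[name]) for name in names},
        n_excluded=n_excluded,
        bits=summarize(bits_samples),
        length=summarize(length_samples),
    )


def category_fraction(
    group: Sequence[str], ann: AnnotationTable, label: str
) -> tuple[int, float, float]:
    """Count and percentage of group members carrying a pathway label.

    Returns (count, percent of members with any pathway assignment,
    percent of all group members) — published category tables mix both
    denominators, so both are reported.
    """
    members = list(group)
    count = sum(1 for p in members if label in ann.labels(p))
    annotated = sum(1 for p in members if ann.labels(p))
    pct_annotated = 100.0 * count / annotated if annotated else 0.0
    pct_all = 100.0 * count / len(members) if members else 0.0
    return count, pct_annotated, pct_all


def location_crosstab(
    groups: Mapping[str, Sequence[str]], ann: AnnotationTable
) -> pd.DataFrame:
    """Per-group counts of nucleus / cytoplasm / membrane / multi-location.

    ``nucleus_plus_other`` counts proteins flagged nucleus together with at
    least one other location.
    """
    rows = {}
    for name, members in groups.items():
        counts = {flag: 0 for flag in LOCATION_FLAGS}
        multi = 0
        for p in members:
            if p not in ann:
                continue
            flags = {flag: ann.location(p, flag) for flag in LOCATION_FLAGS}
            for flag, value in flags.items():
                counts[flag] += int(value)
            if flags["nucleus"] and (flags["cytoplasm"] or flags["membrane"]):
                multi += 1
        counts["nucleus_plus_other"] = multi
        rows[name] = counts
    return pd.DataFrame.from_dict(rows, orient="index").astype(int)


def ratio_chisq(
    observed_top: int,
    observed_bottom: int,
    reference_top: int,
    reference_bottom: int,
) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of an observed top/bottom split
    against a reference ratio, without continuity correction.

    Expected counts are the observed total split in the proportion
    reference_top : reference_bottom.
    """
    for value in (observed_top, observed_bottom, reference_top, reference_bottom):
        if value < 0:
            raise ValueError("counts must be non-negative")
    ref_total = reference_top + reference_bottom
    if ref_total == 0:
        raise ValueError("reference counts are both zero")
    total = observed_top + observed_bottom
    expected_top = total * reference_top / ref_total
    expected_bottom = total * reference_bottom / ref_total
    if expected_top == 0 or expected_bottom == 0:
        raise ValueError("expected cell count is zero")
    chi2 = (
        (observed_top - expected_top) ** 2 / expected_top
        + (observed_bottom - expected_bottom) ** 2 / expected_bottom
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
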