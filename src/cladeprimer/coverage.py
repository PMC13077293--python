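"""Coverage tables: fraction of a reference set amplified per primer and budget.

A coverage evaluation runs the single-primer amplification call for every
(primer, record) pair and reports, for each mismatch budget, the percentage
of records amplified.  Percentages can be stratified by a taxonomic rank
(phylum, order, ...) when records carry lineages; records missing the rank
are grouped under "unidentified" so stratified totals always reconcile with
the overall denominator.

Records shorter than the primer count as non-amplified with the denominator
retained: the denominator is the size of the reference set, not the number
of scannable sequences.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path
from typing import Sequence

import pandas as pd

from .insilico import MatchPolicy, min_mismatch_counts
from .seqcore import UNIDENTIFIED, Primer, RANKS, SeqRecord


def _round2(x: float) -> float:
    """Round-half-even to 2 decimals, as printed in reports."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class CoverageRow:
    primer: str
    budget: int
    n_amplified: int
    n_total: int
    taxon: str | None = None

    @property
    def percent(self) -> float:
        return 100.0 * self.n_amplified / self.n_total


@dataclass
class CoverageTable:
    """Amplified/total counts per (primer, budget), optionally per taxon.

    ``fingerprint`` records the input set (record count and a content hash)
    and the policy, so a report can be traced back to its inputs.
    """

    rows: list[CoverageRow]
    policy: MatchPolicy
    n_records: int
    content_hash: str
    rank: str | None = None
    strata: list[CoverageRow] = field(default_factory=list)

    def row(self, primer: str, budget: int) -> CoverageRow:
        for r in self.rows:
            if r.primer == primer and r.budget == budget:
                return r
        raise KeyError((primer, budget))

    def percent(self, primer: str, budget: int) -> float:
        return self.row(primer, budget).percent

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "primer": r.primer,
                    "budget": r.budget,
                    "n_amplified": r.n_amplified,
                    "n_total": r.n_total,
                    "percent": _round2(r.percent),
                }
                for r in self.rows
            ]
        )

    def strata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": self.rank,
                    "taxon": r.taxon,
                    "primer": r.primer,
                    "budget": r.budget,
                    "n_amplified": r.n_amplified,
                    "n_total": r.n_total,
                    "percent": _round2(r.percent),
                }
                for r in self.strata
            ]
        )

    def _check_invariants(self) -> None:
        by_key: dict[tuple[str, int], CoverageRow] = {}
        for r in self.rows:
            assert 0 <= r.n_amplified <= r.n_total, r
            by_key[(r.primer, r.budget)] = r
        primers = {r.primer for r in self.rows}
        for p in primers:
            budgets = sorted(b for q, b in by_key if q == p)
            for lo, hi in zip(budgets, budgets[1:]):
                assert by_key[(p, lo)].n_amplified <= by_key[(p, hi)].n_amplified, (
                    f"coverage not monotone in budget for {p}"
                )
        if self.strata:
            for p in primers:
                for b in {r.budget for r in self.rows}:
                    tot = sum(
                        r.n_total for r in self.strata
                        if r.primer == p and r.budget == b
                    )
                    assert tot == by_key[(p, b)].n_total


def fingerprint_records(records: Sequence[SeqRecord]) -> str:
    """Order-insensitive content hash of a record set."""
    digests = sorted(
        hashlib.sha256(f"{r.id}\n{r.sequence}".encode()).hexdigest()
        for r in records
    )
    return hashlib.sha256("".join(digests).encode()).hexdigest()[:16]


def coverage_table(
    primers: Sequence[Primer],
    records: Sequence[SeqRecord],
    budgets: Sequence[int],
    policy: MatchPolicy | None = None,
) -> CoverageTable:
    """Evaluate primer coverage of a record set at each mismatch budget.

    One scan per (primer, record) serves every budget: a record amplifies at
    budget b iff its minimal anchor-intact mismatch count is <= b.
    """
    if not primers:
        raise ValueError("no primers given")
    if not records:
        raise ValueError("empty record set: coverage percentage undefined")
    budgets = list(budgets)
    if budgets != sorted(budgets):
        raise ValueError("budgets must be sorted ascending")
    if policy is None:
        policy = MatchPolicy()
    scan_policy = MatchPolicy(
        mismatch_budget=max(budgets),
        anchor_len=policy.anchor_len,
        template_ambiguity=policy.template_ambiguity,
        scan_strand=policy.scan_strand,
        max_amplicon_len=policy.max_amplicon_len,
    )
    rows: list[CoverageRow] = []
    per_record: dict[str, dict[str, int | None]] = {}
    for primer in primers:
        counts = {
            rec.id: min_mismatch_counts(primer, rec, scan_policy) for rec in records
        }
        per_record[primer.name] = counts
        for b in budgets:
            n_amp = sum(1 for c in counts.values() if c is not None and c <= b)
            rows.append(
                CoverageRow(
                    primer=primer.name, budget=b,
                    n_amplified=n_amp, n_total=len(records),
                )
            )
    table = CoverageTable(
        rows=rows,
        policy=policy,
        n_records=len(records),
        content_hash=fingerprint_records(records),
    )
    table._per_record = per_record  # cached for stratification
    table._check_invariants()
    return table


def stratify(
    table: CoverageTable, records: Sequence[SeqRecord], rank: str
) -> CoverageTable:
    """Add per-taxon rows at the given rank to a coverage table.

    Records missing the rank fall into the "unidentified" bucket; every
    record contributes to exactly one taxon, so per-taxon totals sum to the
    overall total.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if table.content_hash != fingerprint_records(records):
        raise ValueError("records do not match the table's input fingerprint")
    taxa: dict[str, list[SeqRecord]] = {}
    any_rank = False
    for rec in records:
        name = rec.lineage.get(rank)
        if name is not None and name != UNIDENTIFIED:
            any_rank = True
        taxa.setdefault(name or UNIDENTIFIED, []).append(rec)
    if not any_rank:
        raise ValueError(f"no record carries rank {rank!r}")
    per_record: dict[str, dict[str, int | None]] = getattr(table, "_per_record", {})
    budgets = sorted({r.budget for r in table.rows})
    strata: list[CoverageRow] = []
    for taxon in sorted(taxa):
        members = taxa[taxon]
        for primer_name, counts in per_record.items():
            for b in budgets:
                n_amp = sum(
                    1 for m in members
                    if counts[m.id] is not None and counts[m.id] <= b
                )
                strata.append(
                    CoverageRow(
                        primer=primer_name, budget=b, taxon=taxon,
                        n_amplified=n_amp, n_total=len(members),
                    )
                )
    out = CoverageTable(
        rows=list(table.rows),
        policy=table.policy,
        n_records=table.n_records,
        content_hash=table.content_hash,
        rank=rank,
        strata=strata,
    )
    out._per_record = per_record
    out._check_invariants()
    return out


_TSV_HEADER = "primer\tbudget\tn_amplified\tn_total\tpercent"


def write_report(table: CoverageTable, path: str | Path, format: str = "tsv") -> None:
    """Write a coverage report; byte-stable for identical inputs.

    TSV has the fixed header ``primer  budget  n_amplified  n_total
    percent`` (percent to 2 decimals, half-even); a stratified section
    follows after a blank line when present.  JSON carries the same rows
    plus the policy snapshot and input fingerprint, and round-trips via
    :func:`read_report_json`.
    """
    path = Path(path)
    if format == "tsv":
        lines = [_TSV_HEADER]
        for r in table.rows:
            lines.append(
                f"{r.primer}\t{r.budget}\t{r.n_amplified}\t{r.n_total}\t"
                f"{_round2(r.percent):.2f}"
            )
        if table.strata:
            lines.append("")
            lines.append("rank\ttaxon\t" + _TSV_HEADER)
            for r in table.strata:
                lines.append(
                    f"{table.rank}\t{r.taxon}\t{r.primer}\t{r.budget}\t"
                    f"{r.n_amplified}\t{r.n_total}\t{_round2(r.percent):.2f}"
                )
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "policy": {
                "mismatch_budget": table.policy.mismatch_budget,
                "anchor_len": table.policy.anchor_len,
                "template_ambiguity": table.policy.template_ambiguity,
                "scan_strand": table.policy.scan_strand,
                "max_amplicon_len": table.policy.max_amplicon_len,
            },
            "n_records": table.n_records,
            "content_hash": table.content_hash,
            "rank": table.rank,
            "rows": [
                {
                    "primer": r.primer, "budget": r.budget,
                    "n_amplified": r.n_amplified, "n_total": r.n_total,
                    "percent": _round2(r.percent),
                }
                for r in table.rows
            ],
            "strata": [
                {
                    "taxon": r.taxon, "primer": r.primer, "budget": r.budget,
                    "n_amplified": r.n_amplified, "n_total": r.n_total,
                    "percent": _round2(r.percent),
                }
                for r in table.strata
            ],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> CoverageTable:
    """Read back a JSON coverage report (inverse of ``write_report``)."""
    payload = json.loads(Path(path).read_text())
    rows = [
        CoverageRow(
            primer=r["primer"], budget=r["budget"],
            n_amplified=r["n_amplified"], n_total=r["n_total"],
        )
        for r in payload["rows"]
    ]
    strata = [
        CoverageRow(
            primer=r["primer"], budget=r["budget"], taxon=r["taxon"],
            n_amplified=r["n_amplified"], n_total=r["n_total"],
        )
        for r in payload.get("strata", [])
    ]
    return CoverageTable(
        rows=rows,
        policy=MatchPolicy(**payload["policy"]),
        n_records=payload["n_records"],
        content_hash=payload["content_hash"],
        rank=payload.get("rank"),
        strata=strata,
    )
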