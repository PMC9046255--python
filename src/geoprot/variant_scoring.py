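"""Zero-shot mutational-effect scoring via masked marginals.

A variant with mutation set M is scored by masking all mutated positions of
the wildtype sequence in a single forward pass of a masked protein language
model and summing, over the mutated positions, the difference in
log-probability between the mutant and wildtype amino acid under the
resulting joint-mask distributions:

    score(M) = sum_{i in M} [ log p(x_i = mt_i | x_\\M) - log p(x_i = wt_i | x_\\M) ]

The language-model head is used as loaded (out-of-the-box or fine-tuned);
it is never retrained. Substitutions only — insertions and deletions are
rejected, since position-wise masking has no alignment to offer them.
Agreement with assay values is measured by Spearman's rank correlation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .metrics import spearman_rho
from .structure_io import AA_TO_INDEX

Mutation = tuple[int, str, str]  # (1-based position, wildtype AA, mutant AA)

_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass
class MutScanRecord:
    """One variant: a non-empty mutation set and its assay value."""

    mutations: list[Mutation]
    assay: float
    is_wildtype: bool = False

    def __post_init__(self):
        if not self.mutations and not self.is_wildtype:
            raise ValueError("mutation set empty for a non-wildtype record")

    def notation(self) -> str:
        return ";".join(f"{wt}{pos}{mt}" for pos, wt, mt in self.mutations) or "WT"


@dataclass
class MutScanTable:
    """A wildtype sequence plus scored variants."""

    wildtype: str
    records: list[MutScanRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for rec in self.records:
            validate_mutations(self.wildtype, rec.mutations)

    def __len__(self):
        return len(self.records)


def validate_mutations(wildtype: str, mutations: list[Mutation]) -> None:
    for pos, wt, mt in mutations:
        if not 1 <= pos <= len(wildtype):
            raise ValueError(f"position {pos} outside [1, {len(wildtype)}]")
        if wildtype[pos - 1] != wt:
            raise ValueError(
                f"wildtype mismatch at position {pos}: sequence has "
                f"{wildtype[pos - 1]!r}, mutation says {wt!r}")
        if wt not in AA_TO_INDEX or mt not in AA_TO_INDEX:
            raise ValueError(f"invalid amino acid in mutation {wt}{pos}{mt}")


def parse_mutation_notation(text: str) -> list[Mutation]:
    """Parse ``"A123G"`` / ``"A123G;T45K"`` notation (wt, 1-based pos, mt)."""
    text = text.strip()
    if text in ("", "WT", "wt"):
        return []
    muts = []
    for token in text.split(";"):
        m = _MUT_RE.match(token.strip())
        if not m:
            raise ValueError(f"cannot parse mutation token {token!r}")
        muts.append((int(m.group(2)), m.group(1), m.group(3)))
    return muts


def read_mutscan_tsv(tsv_text: str, wildtype: str) -> MutScanTable:
    """Parse a TSV with columns ``mutations<TAB>assay`` (header optional)."""
    records = []
    for line in tsv_text.strip().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if cols[0].lower() in ("mutations", "mutation"):
            continue
        muts = parse_mutation_notation(cols[0])
        records.append(MutScanRecord(mutations=muts, assay=float(cols[1]),
                                     is_wildtype=not muts))
    return MutScanTable(wildtype=wildtype, records=records)


def write_scores_tsv(table: MutScanTable, scores: np.ndarray) -> str:
    lines = ["mutations\tassay\tscore"]
    for rec, s in zip(table.records, scores):
        lines.append(f"{rec.notation()}\t{rec.assay:.6g}\t{s:.6g}")
    return "\n".join(lines) + "\n"


def masked_marginal_score(lm, wt_sequence: str, mutations: list[Mutation]) -> float:
    """Joint masked-marginal score of one mutation set.

    All mutated positions are masked simultaneously in one forward pass;
    the returned score is the sum over positions of
    ``log p(mt) - log p(wt)`` under that joint-mask distribution. A set
    whose mutants equal the wildtype scores exactly 0. Invariant to the
    order in which mutations are listed.
    """
    validate_mutations(wt_sequence, mutations)
    if not mutations:
        return 0.0
    positions = [pos for pos, _, _ in mutations]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate positions in mutation set")
    dist = lm.masked_logprobs(wt_sequence, positions)
    score = 0.0
    for pos, wt, mt in mutations:
        p_mt = dist.prob_of(pos, mt)
        p_wt = dist.prob_of(pos, wt)
        score += float(np.log(p_mt) - np.log(p_wt))
    return score


def score_scan(lm, table: MutScanTable) -> np.ndarray:
    """Masked-marginal scores for every record of a scan table."""
    return np.array([
        masked_marginal_score(lm, table.wildtype, rec.mutations)
        for rec in table.records
    ])


def scan_correlation(scores: np.ndarray, assay: np.ndarray) -> float:
    """Spearman rho between model scores and assay values (NaN if undefined)."""
    scores = np.asarray(scores, dtype=float)
    assay = np.asarray(assay, dtype=float)
    if len(scores) < 3:
        raise ValueError("need at least 3 records for a rank correlation")
    return spearman_rho(scores, assay)
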