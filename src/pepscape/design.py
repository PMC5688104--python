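"""Rule-based peptide redesign and anchor-conservation checks.

MDM2-binding peptides bury a Phe/Trp/Leu anchor triad in the receptor
groove; any redesign must leave those anchors (and, by policy, charged
residues implicated in binding) untouched. Design rules are simple
transformations -- delete a position, substitute a position from an option
set -- and the candidate set is the cross product of the per-position
options. Candidates are ranked by a mean per-residue helix-propensity
score using a bundled, configurable 0-1 scale that preserves the standard
qualitative ranking Ala > Arg > Leu > ... > Gly > Pro.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import pandas as pd

from .geometry import PeptideSequence

# 1-based anchor positions and expected residues in the phage-derived
# 12-mer numbering (F4 / W8 / L11).
DEFAULT_ANCHORS = {4: "F", 8: "W", 11: "L"}

TWELVE_ONE = PeptideSequence("12/1", "MPRFMDYWEGLN")
TWELVE_ONE_M = PeptideSequence("12/1m", "TRFADLWELLN")


class DesignError(ValueError):
    """A rule violates the design constraints (locked position etc.)."""


@dataclass(frozen=True)
class DesignRule:
    """One transformation of the starting sequence.

    kind 'delete' removes a position; kind 'substitute' offers one or more
    replacement residues at a position. Positions are 1-based in the
    starting sequence.
    """

    rule_id: str
    description: str
    kind: str                       # "delete" | "substitute"
    position: int
    options: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("delete", "substitute"):
            raise DesignError(f"unknown rule kind {self.kind!r}")
        if self.kind == "substitute" and not self.options:
            raise DesignError("substitution rule needs at least one option")


@dataclass(frozen=True)
class DesignProposal:
    """A candidate sequence with the rules that produced it and its score."""

    sequence: PeptideSequence
    applied_rules: tuple[str, ...]
    propensity: float


def twelve_one_rule_set() -> list[DesignRule]:
    """The four redesign rules for the 12/1 peptide.

    (i) replace the helix-disrupting Pro2; (ii) drop the dispensable Met1;
    (iii) replace Met5, which populates a left-handed helix; (iv) replace
    Tyr7 (beta-prone) by Leu, and Gly10 by Leu, to push the sequence
    toward helix.
    """
    return [
        DesignRule("i", "Pro disrupts the helix: P2 -> T", "substitute",
                   2, ("T",)),
        DesignRule("ii", "Met1 makes no stable receptor contact: delete",
                   "delete", 1),
        DesignRule("iii", "Met5 populates a left-handed helix: M5 -> A",
                   "substitute", 5, ("A",)),
        DesignRule("iv-a", "Tyr7 is beta-prone: Y7 -> L", "substitute",
                   7, ("L",)),
        DesignRule("iv-b", "Gly10 has low helix propensity: G10 -> L",
                   "substitute", 10, ("L",)),
    ]


def locked_positions(seq: PeptideSequence,
                     anchors: dict[int, str] = DEFAULT_ANCHORS
                     ) -> set[int]:
    """Anchor positions plus charged residues (D, E, K, R), 1-based."""
    locked = set(anchors)
    for i, aa in enumerate(seq.residues, start=1):
        if aa in "DEKR":
            locked.add(i)
    return locked


def apply_design_rules(seq: PeptideSequence = TWELVE_ONE,
                       rules: list[DesignRule] | None = None,
                       anchors: dict[int, str] = DEFAULT_ANCHORS
                       ) -> list[DesignProposal]:
    """All candidate sequences from the cross product of the rule options.

    Substitution options multiply; deletions always apply. With no rules
    the sole candidate is the input sequence. Rules touching a locked
    position (anchor or charged residue) are rejected.
    """
    rules = list(rules) if rules is not None else []
    locked = locked_positions(seq, anchors)
    n = len(seq)
    subs: list[DesignRule] = []
    deletions: list[DesignRule] = []
    for rule in rules:
        if not 1 <= rule.position <= n:
            raise DesignError(f"rule {rule.rule_id}: position "
                              f"{rule.position} outside sequence")
        if rule.position in locked:
            raise DesignError(
                f"rule {rule.rule_id}: position {rule.position} "
                f"({seq.residues[rule.position - 1]}) is locked")
        (subs if rule.kind == "substitute" else deletions).append(rule)

    scale = load_propensity_scale()
    deleted = {r.position for r in deletions}
    proposals = []
    option_sets = [[(r, o) for o in r.options] for r in subs]
    for combo in product(*option_sets):
        residues = list(seq.residues)
        applied = [r.rule_id for r in deletions]
        for rule, option in combo:
            residues[rule.position - 1] = option
            applied.append(rule.rule_id)
        candidate = "".join(aa for i, aa in enumerate(residues, start=1)
                            if i not in deleted)
        cand_seq = PeptideSequence(f"{seq.name}-design", candidate)
        proposals.append(DesignProposal(
            sequence=cand_seq,
            applied_rules=tuple(sorted(applied)),
            propensity=propensity_score(cand_seq, scale)))
    proposals.sort(key=lambda p: (-p.propensity, p.sequence.residues))
    return proposals


def load_propensity_scale(path=None) -> dict[str, float]:
    """The bundled (or a user-supplied) per-residue helix-propensity table."""
    if path is None:
        src = resources.files("pepscape.data").joinpath(
            "helix_propensity.tsv")
        with src.open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return dict(zip(table["residue"], table["propensity"]))


def propensity_score(seq: PeptideSequence,
                     scale: dict[str, float] | None = None) -> float:
    """Mean per-residue helix propensity; higher means more helical."""
    if scale is None:
        scale = load_propensity_scale()
    missing = [aa for aa in set(seq.residues) if aa not in scale]
    if missing:
        raise DesignError(f"residues missing from scale: {sorted(missing)}")
    return sum(scale[aa] for aa in seq.residues) / len(seq)


def check_anchor_conservation(seqs: list[PeptideSequence],
                              anchors: dict[int, str] = DEFAULT_ANCHORS
                              ) -> pd.DataFrame:
    """Per-sequence anchor check: True iff every anchor matches.

    ``anchors`` maps 1-based offsets to expected one-letter codes (shift
    the offsets for sequences whose numbering changed, e.g. after an
    N-terminal deletion).
    """
    max_off = max(anchors)
    rows = []
    for seq in seqs:
        if len(seq) < max_off:
            raise DesignError(
                f"{seq.name}: shorter than anchor offset {max_off}")
        ok = all(seq.residues[pos - 1] == aa for pos, aa in anchors.items())
        rows.append({"name": seq.name, "sequence": seq.residues,
                     "anchors_conserved": ok})
    return pd.DataFrame(rows)
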