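"""Pilot-array probe ranking: pick one oligo probe per transcript.

Platforms are designed with up to seven candidate probes per transcript and
a pilot hybridization decides which one goes on the production array.  The
ranking uses the green (Cy3) channel, which runs consistently brighter than
the red, and scores each probe by its intensity divided by the median
intensity of all of the transcript's probes.  The rules by candidate count:

* 1 probe: pass through, with a QC check that both dye channels clear the
  array background.
* 2 probes: keep the brighter one.
* 3-6 probes: keep the highest-ratio probe if its ratio is below the cutoff
  (default 3), otherwise the second-highest ratio (the top probe is treated
  as an outlier).
* 7 probes: as above, but when the top ratio exceeds the cutoff that probe
  is removed, ratios are recomputed over the remaining six, and the new
  highest-ratio probe wins.  The removal happens at most once.

The intent is to keep the brightest probe that is not an outlier.  Ties are
broken toward the earliest probe in input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

BACKGROUND_INTENSITY = 300.0

CATEGORIES = ("EWGM", "EWOGM", "GM", "GMRWOM")


class ProbeSelectionError(ValueError):
    pass


@dataclass
class ProbeCandidate:
    transcript_id: str
    probe_id: str
    green: float
    red: float = 0.0
    category: str = "GM"

    def __post_init__(self) -> None:
        if self.green < 0 or self.red < 0:
            raise ProbeSelectionError(
                f"negative intensity for probe {self.probe_id!r}"
            )


@dataclass
class ProbeChoice:
    transcript_id: str
    chosen_probe_id: str
    rule_applied: str  # single | pair_max | ratio_3to6 | ratio_7_with_removal
    ratios: dict = field(default_factory=dict)
    removed_probe_id: Optional[str] = None
    qc_flags: list = field(default_factory=list)


def compute_ratios(intensities: Sequence[float]) -> list[float]:
    """intensity / median over ALL the transcript's probes (self included)."""
    vals = np.asarray(list(intensities), dtype=float)
    if vals.size == 0:
        raise ProbeSelectionError("no intensities given")
    med = float(np.median(vals))
    if med == 0:
        raise ProbeSelectionError("degenerate transcript: all-zero probe intensities")
    return [float(v / med) for v in vals]


def _argmax_first(values: Sequence[float]) -> int:
    """Index of the maximum, ties going to the earliest entry."""
    return int(np.argmax(values))


def select_probe(
    candidates: Sequence[ProbeCandidate],
    ratio_cutoff: float = 3.0,
    background: float = BACKGROUND_INTENSITY,
) -> ProbeChoice:
    """Apply the count-dependent ranking rule to one transcript's candidates."""
    n = len(candidates)
    if n == 0:
        raise ProbeSelectionError("transcript has no candidate probes")
    if n > 7:
        raise ProbeSelectionError(
            f"transcript has {n} candidate probes; the rule table covers 1-7"
        )
    tid = candidates[0].transcript_id
    ids = [c.probe_id for c in candidates]
    if len(set(ids)) != n:
        raise ProbeSelectionError(f"duplicate probe ids for transcript {tid!r}")
    green = [c.green for c in candidates]

    if n == 1:
        c = candidates[0]
        flags = []
        if c.green < background or c.red < background:
            flags.append("single_probe_low_intensity")
        return ProbeChoice(tid, c.probe_id, "single", qc_flags=flags)

    if n == 2:
        return ProbeChoice(tid, ids[_argmax_first(green)], "pair_max")

    ratios = compute_ratios(green)
    order = sorted(range(n), key=lambda i: (-ratios[i], i))
    if n <= 6:
        flags = []
        if ratios[order[0]] < ratio_cutoff:
            chosen = order[0]
        else:
            chosen = order[1]
            if ratios[chosen] >= ratio_cutoff:
                flags.append("second_ratio_above_cutoff")
        return ProbeChoice(tid, ids[chosen], "ratio_3to6",
                           ratios=dict(zip(ids, ratios)), qc_flags=flags)

    # n == 7: one removal-and-recompute pass when the top ratio is an outlier
    if ratios[order[0]] > ratio_cutoff:
        removed = order[0]
        rest = [i for i in range(n) if i != removed]
        new_ratios = compute_ratios([green[i] for i in rest])
        chosen = rest[_argmax_first(new_ratios)]
        return ProbeChoice(
            tid, ids[chosen], "ratio_7_with_removal",
            ratios=dict(zip([ids[i] for i in rest], new_ratios)),
            removed_probe_id=ids[removed],
        )
    chosen = order[0]
    return ProbeChoice(tid, ids[chosen], "ratio_7_with_removal",
                       ratios=dict(zip(ids, ratios)))


def select_platform(
    pilot: Sequence[ProbeCandidate],
    ratio_cutoff: float = 3.0,
    background: float = BACKGROUND_INTENSITY,
) -> tuple[list[ProbeChoice], dict]:
    """Select one probe per transcript and tally rules and categories.

    Candidates are grouped by transcript in input order.  Returns the
    choices plus a summary with per-rule and per-category counts.
    """
    by_transcript: dict[str, list[ProbeCandidate]] = {}
    for cand in pilot:
        by_transcript.setdefault(cand.transcript_id, []).append(cand)
    choices = []
    rule_counts: dict[str, int] = {}
    category_counts: dict[str, int] = {}
    for tid, cands in by_transcript.items():
        try:
            choice = select_probe(cands, ratio_cutoff=ratio_cutoff,
                                  background=background)
        except ProbeSelectionError as exc:
            raise ProbeSelectionError(f"transcript {tid!r}: {exc}") from exc
        choices.append(choice)
        rule_counts[choice.rule_applied] = rule_counts.get(choice.rule_applied, 0) + 1
        cat = cands[0].category
        category_counts[cat] = category_counts.get(cat, 0) + 1
    summary = {"n_transcripts": len(choices),
               "rules": rule_counts, "categories": category_counts}
    return choices, summary
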