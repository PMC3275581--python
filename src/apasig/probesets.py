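"""Partition transcript probes into 5' and 3' probesets around APA sites.

This is the custom chip-description step: every alternative polyadenylation
(APA) site splits its transcript's mRNA into a proximal fragment (covered by
both the short and long 3'UTR isoform) and a distal fragment (long isoform
only).  Probes fully inside the proximal fragment form the 5' probeset,
probes fully inside the distal fragment the 3' probeset, and a pair is kept
only when both sides have at least ``min_probes`` probes.

Coordinates are 0-based, half-open, in the mRNA frame.  An APA position is
the first base of the distal fragment, so a probe ending exactly at the
position belongs to the 5' side; probes spanning the position hybridize both
isoforms with partial affinity and are excluded from both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TranscriptModel",
    "Probe",
    "ProbesetPair",
    "ProbesetRejection",
    "BuildReport",
    "split_probes",
    "build_all",
    "pairs_to_frame",
]

DEFAULT_MIN_PROBES = 3


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's mRNA coordinate frame with its APA site positions."""

    transcript_id: str
    gene_id: str
    length: int
    apa_positions: tuple[int, ...]
    utr3_start: int | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"{self.transcript_id}: non-positive mRNA length")
        pos = tuple(int(p) for p in self.apa_positions)
        if any(not (0 < p < self.length) for p in pos):
            raise ValueError(f"{self.transcript_id}: APA position outside (0, length)")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{self.transcript_id}: APA positions not strictly increasing")
        object.__setattr__(self, "apa_positions", pos)


@dataclass(frozen=True)
class Probe:
    probe_id: str
    transcript_id: str
    start: int
    length: int = 25

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class ProbesetPair:
    """Accepted 5'/3' probeset pair for one APA site."""

    apa_id: str
    transcript_id: str
    position: int
    probes_5p: tuple[str, ...]
    probes_3p: tuple[str, ...]
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProbesetRejection:
    apa_id: str
    transcript_id: str
    position: int
    n_5p: int
    n_3p: int
    n_excluded: int
    reasons: tuple[str, ...]


@dataclass
class BuildReport:
    """Outcome counts of a full probeset build."""

    n_pairs: int = 0
    n_transcripts_with_pair: int = 0
    n_transcripts_multi_pair: int = 0
    rejections: list[ProbesetRejection] = field(default_factory=list)
    #: probe ids appearing in probesets of more than one APA of a transcript
    shared_probes: dict[str, int] = field(default_factory=dict)

    @property
    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rej in self.rejections:
            for r in rej.reasons:
                counts[r] = counts.get(r, 0) + 1
        return counts

    def rejections_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "apa_id": r.apa_id,
                    "transcript_id": r.transcript_id,
                    "position": r.position,
                    "n_5p": r.n_5p,
                    "n_3p": r.n_3p,
                    "n_excluded": r.n_excluded,
                    "reasons": ";".join(r.reasons),
                }
                for r in self.rejections
            ],
            columns=["apa_id", "transcript_id", "position", "n_5p", "n_3p", "n_excluded", "reasons"],
        )


def apa_id(transcript_id: str, position: int) -> str:
    return f"{transcript_id}:{int(position)}"


def split_probes(
    transcript: TranscriptModel,
    probes: Sequence[Probe],
    apa_position: int,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> ProbesetPair | ProbesetRejection:
    """Split ``probes`` into 5'/3' probesets around one APA site.

    Returns a :class:`ProbesetPair` when both sides have at least
    ``min_probes`` probes, otherwise a :class:`ProbesetRejection` recording
    the failing side(s).
    """
    if not (0 < apa_position < transcript.length):
        raise ValueError(
            f"APA position {apa_position} outside (0, {transcript.length}) "
            f"for {transcript.transcript_id}"
        )
    ordered = sorted(probes, key=lambda p: (p.start, p.probe_id))
    p5: list[str] = []
    p3: list[str] = []
    spanning: list[str] = []
    for probe in ordered:
        if probe.transcript_id != transcript.transcript_id:
            raise ValueError(f"probe {probe.probe_id} does not belong to {transcript.transcript_id}")
        if probe.start < 0 or probe.end > transcript.length:
            raise ValueError(f"probe {probe.probe_id} out of transcript bounds")
        if probe.end <= apa_position:
            p5.append(probe.probe_id)
        elif probe.start >= apa_position:
            p3.append(probe.probe_id)
        else:
            spanning.append(probe.probe_id)
    aid = apa_id(transcript.transcript_id, apa_position)
    if len(p5) >= min_probes and len(p3) >= min_probes:
        return ProbesetPair(aid, transcript.transcript_id, int(apa_position),
                            tuple(p5), tuple(p3), tuple(spanning))
    reasons = []
    if len(p5) == 0:
        reasons.append("all_probes_distal")
    elif len(p5) < min_probes:
        reasons.append("too_few_5p")
    if len(p3) == 0:
        reasons.append("all_probes_proximal")
    elif len(p3) < min_probes:
        reasons.append("too_few_3p")
    return ProbesetRejection(aid, transcript.transcript_id, int(apa_position),
                             len(p5), len(p3), len(spanning), tuple(reasons))


def transcripts_from_frame(frame: pd.DataFrame) -> list[TranscriptModel]:
    """Build transcript models from an annotation table.

    Expects columns ``transcript_id, gene_id, length, apa_positions`` with
    APA positions either comma-separated strings or sequences.
    """
    out = []
    for row in frame.itertuples(index=False):
        pos = row.apa_positions
        if isinstance(pos, str):
            pos = tuple(int(p) for p in pos.split(",") if p != "")
        else:
            pos = tuple(int(p) for p in pos)
        utr3 = int(row.utr3_start) if "utr3_start" in frame.columns else None
        out.append(TranscriptModel(row.transcript_id, row.gene_id, int(row.length), pos, utr3))
    return out


def probes_from_frame(frame: pd.DataFrame) -> list[Probe]:
    if frame["probe_id"].duplicated().any():
        dupes = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe ids: {dupes[:5]}")
    return [
        Probe(r.probe_id, r.transcript_id, int(r.start), int(r.length))
        for r in frame.itertuples(index=False)
    ]


def probes_from_bed(frame: pd.DataFrame) -> list[Probe]:
    """Probes from a BED-like table: chrom = transcript id, start, end, name
    (first four columns, positional)."""
    cols = frame.columns[:4]
    return [
        Probe(str(name), str(tid), int(start), int(end) - int(start))
        for tid, start, end, name in frame[cols].itertuples(index=False)
    ]


def build_all(
    transcripts: Iterable[TranscriptModel] | pd.DataFrame,
    probes: Iterable[Probe] | pd.DataFrame,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> tuple[list[ProbesetPair], BuildReport]:
    """Attempt one probeset pair per (transcript, APA site).

    Multi-APA transcripts yield one independent binary split per site; a
    probe upstream of several sites then belongs to several 5' probesets,
    which is recorded in ``report.shared_probes``.
    """
    if isinstance(transcripts, pd.DataFrame):
        transcripts = transcripts_from_frame(transcripts)
    if isinstance(probes, pd.DataFrame):
        probes = probes_from_frame(probes)
    else:
        probes = list(probes)
        seen: set[str] = set()
        for p in probes:
            if p.probe_id in seen:
                raise ValueError(f"duplicate probe id: {p.probe_id}")
            seen.add(p.probe_id)

    by_transcript: dict[str, list[Probe]] = {}
    for p in probes:
        by_transcript.setdefault(p.transcript_id, []).append(p)
    known = {t.transcript_id for t in transcripts}
    unknown = set(by_transcript) - known
    if unknown:
        raise ValueError(f"probes reference unknown transcripts: {sorted(unknown)[:5]}")

    pairs: list[ProbesetPair] = []
    report = BuildReport()
    for tr in transcripts:
        tr_probes = by_transcript.get(tr.transcript_id, [])
        accepted_here: list[ProbesetPair] = []
        usage: dict[str, int] = {}
        for pos in tr.apa_positions:
            result = split_probes(tr, tr_probes, pos, min_probes=min_probes)
            if isinstance(result, ProbesetPair):
                accepted_here.append(result)
                for pid in result.probes_5p + result.probes_3p:
                    usage[pid] = usage.get(pid, 0) + 1
            else:
                report.rejections.append(result)
        pairs.extend(accepted_here)
        if accepted_here:
            report.n_transcripts_with_pair += 1
        if len(accepted_here) >= 2:
            report.n_transcripts_multi_pair += 1
            for pid, k in usage.items():
                if k > 1:
                    report.shared_probes[pid] = k
    report.n_pairs = len(pairs)
    return pairs, report


def pairs_to_frame(pairs: Sequence[ProbesetPair]) -> pd.DataFrame:
    """Long-format probeset definition table: apa_id, side (5p|3p), probe_id."""
    rows = []
    for pair in pairs:
        for pid in pair.probes_5p:
            rows.append((pair.apa_id, "5p", pid))
        for pid in pair.probes_3p:
            rows.append((pair.apa_id, "3p", pid))
    return pd.DataFrame(rows, columns=["apa_id", "side", "probe_id"])


def pairs_from_frame(frame: pd.DataFrame) -> list[ProbesetPair]:
    """Inverse of :func:`pairs_to_frame` (positions parsed from the apa_id)."""
    pairs = []
    for aid, grp in frame.groupby("apa_id", sort=False):
        tid, pos = aid.rsplit(":", 1)
        p5 = tuple(grp.loc[grp["side"] == "5p", "probe_id"])
        p3 = tuple(grp.loc[grp["side"] == "3p", "probe_id"])
        pairs.append(ProbesetPair(aid, tid, int(pos), p5, p3))
    return pairs
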