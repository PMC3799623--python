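"""Simple indel coding: gap runs in exon alignments as binary characters.

Each distinct maximal gap run — identified by its exact (start, end)
alignment coordinates — is one event shared by every taxon carrying that
run; runs touching either alignment end (terminal gaps, usually missing
data) are ignored.  Events are coded 1 = gap present, and a
"potentially informative" event is parsimony-informative: at least two
taxa in each state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import GAP, Msa


@dataclass
class IndelEvent:
    region: str
    columns: tuple[int, int]  # half-open alignment coords
    presence: dict[str, bool]
    length: int


def _gap_runs(row: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, ch in enumerate(row):
        if ch == GAP and start is None:
            start = i
        elif ch != GAP and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def extract_indel_events(msa: Msa) -> list[IndelEvent]:
    """All distinct internal gap-run signatures of an aligned region."""
    ncol = msa.n_columns
    sigs: dict[tuple[int, int], set[str]] = {}
    for taxon, row in msa.rows.items():
        for s, e in _gap_runs(row):
            if s == 0 or e == ncol:
                continue  # terminal gap
            sigs.setdefault((s, e), set()).add(taxon)
    events = []
    for (s, e), carriers in sorted(sigs.items()):
        if len(carriers) == len(msa.taxa):
            continue  # no taxon without the gap: not an event
        events.append(IndelEvent(
            region=msa.region, columns=(s, e),
            presence={t: t in carriers for t in msa.taxa}, length=e - s))
    return events


def informative_events(events: list[IndelEvent]) -> list[IndelEvent]:
    """Events with at least two taxa in each state."""
    out = []
    for ev in events:
        with_gap = sum(ev.presence.values())
        without = len(ev.presence) - with_gap
        if with_gap >= 2 and without >= 2:
            out.append(ev)
    return out


def code_binary(events: list[IndelEvent], taxa: list[str],
                informative_only: bool = False) -> pd.DataFrame:
    """Binary taxa x events matrix (1 = gap present), columns ordered by
    (region, start)."""
    if informative_only:
        events = informative_events(events)
    events = sorted(events, key=lambda e: (e.region, e.columns))
    data = np.zeros((len(taxa), len(events)), dtype=int)
    cols = []
    for j, ev in enumerate(events):
        cols.append(f"{ev.region}:{ev.columns[0]}-{ev.columns[1]}")
        for i, t in enumerate(taxa):
            data[i, j] = int(ev.presence.get(t, False))
    return pd.DataFrame(data, index=taxa, columns=cols)
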