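"""Error-tolerant adapter/linker trimming of junction reads.

The amplicons carry vector LTR sequence at the 5' end and the ligation
linker at the 3' end of the genomic insert.  Both are located by a
semiglobal edit-distance search (substitutions and indels) and removed; a
match is accepted when its edit distance is at most
``floor(error_rate * matched_adapter_length)``, where the matched length is
measured on the adapter side (adapters may run off either read end, down to
a minimum overlap).  Reads in which neither adapter is found are discarded
by default, as are reads trimmed below the minimum length.

Match selection is a total order so results are reproducible and checkable
against a brute-force enumeration: among accepted matches the one with the
smallest edit distance wins; ties break to the leftmost span for the 5'
adapter and the rightmost-starting span for the 3' adapter, then to the
smaller end coordinate, then to the longer matched adapter portion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import TrimConfig
from .synthetic import ReadRecord

__all__ = ["AdapterMatch", "find_adapter", "trim_reads", "read_fastq", "write_fastq"]


@dataclass(frozen=True)
class AdapterMatch:
    start: int          # span start in the read (0-based)
    stop: int           # span end, half-open
    distance: int       # edit distance of adapter portion vs span
    matched_len: int    # length of the adapter portion that was aligned


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode(), dtype=np.uint8)


_N = ord("N")


def _dp_last_row(query: np.ndarray, text: np.ndarray, free_start: bool) -> np.ndarray:
    """Last row of the edit-distance DP of ``query`` against prefixes of
    ``text``.  Entry j is the minimum distance of query against a span of
    text ending at j, with the span start free (``free_start``) or anchored
    at 0.  'N' on either side never matches."""
    n = len(text)
    j_idx = np.arange(1, n + 1)
    row = np.zeros(n + 1) if free_start else np.arange(n + 1, dtype=float)
    for i, q in enumerate(query, start=1):
        sub = ((text != q) | (text == _N) | (q == _N)).astype(float)
        t = np.minimum(row[:-1] + sub, row[1:] + 1.0)  # diag, up
        h = np.concatenate(([float(i)], t - j_idx))
        new = np.concatenate(([0.0], j_idx)) + np.minimum.accumulate(h)
        row = new
    return row


def _best_anchored_stop(query: np.ndarray, text: np.ndarray, target: int) -> int:
    """Smallest stop such that the global distance of query vs text[:stop]
    equals ``target`` (caller guarantees one exists)."""
    row = _dp_last_row(query, text, free_start=False)
    hits = np.flatnonzero(row == target)
    return int(hits[0])


def find_adapter(
    read_sequence: str,
    adapter: str,
    error_rate: float,
    *,
    end: str = "5p",
    min_overlap: int = 3,
) -> AdapterMatch | None:
    """Locate ``adapter`` in ``read_sequence`` by semiglobal edit distance.

    ``end`` selects the geometry: a 5' adapter may additionally be truncated
    at the read start (suffix of the adapter matching a read prefix), a 3'
    adapter at the read end.  Returns the best accepted match under the
    module's total order, or None.
    """
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not read_sequence:
        return None
    a = _encode(adapter)
    r = _encode(read_sequence)
    m, n = len(a), len(r)

    candidates: list[tuple[tuple, AdapterMatch]] = []

    def key(match: AdapterMatch) -> tuple:
        if end == "5p":
            return (match.distance, match.start, match.stop, -match.matched_len)
        return (match.distance, -match.start, match.stop, -match.matched_len)

    def consider(match: AdapterMatch) -> None:
        if match.distance <= int(np.floor(error_rate * match.matched_len)):
            candidates.append((key(match), match))

    # --- full adapter, span free at both ends ---
    if m >= min_overlap:
        row_rev = _dp_last_row(a[::-1], r[::-1], free_start=True)
        per_start = row_rev[::-1]  # per_start[s] = best distance of a match starting at s
        d_int = int(per_start.min())
        starts = np.flatnonzero(per_start == d_int)
        s = int(starts[0] if end == "5p" else starts[-1])
        stop = s + _best_anchored_stop(a, r[s:], d_int)
        consider(AdapterMatch(s, stop, d_int, m))

    # --- 5' overhang: adapter suffix anchored at read start ---
    if end == "5p":
        for k in range(1, m - min_overlap + 1):
            portion = a[k:]
            row = _dp_last_row(portion, r, free_start=False)
            d = int(row.min())
            stop = int(np.flatnonzero(row == d)[0])
            consider(AdapterMatch(0, stop, d, len(portion)))
    # --- 3' overhang: adapter prefix anchored at read end ---
    else:
        for k in range(min_overlap, m):
            portion = a[:k][::-1]
            row = _dp_last_row(portion, r[::-1], free_start=False)
            d = int(row.min())
            span = int(np.flatnonzero(row == d)[0])
            consider(AdapterMatch(n - span, n, d, k))

    if not candidates:
        return None
    return min(candidates)[1]


def trim_reads(
    reads: Iterable[ReadRecord],
    trim_config: TrimConfig,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Trim the 5' LTR and 3' linker from each read.

    The 5' match is removed through its end, the 3' match from its start
    onward; qualities are cut in register.  Returns the surviving reads and
    a per-read disposition log (read_id, action, trimmed_length) where
    action is one of trimmed / untrimmed_discarded / untrimmed_kept /
    too_short.
    """
    kept: list[ReadRecord] = []
    log_rows = []
    for read in reads:
        seq, qual = read.sequence, read.qualities
        ltr = find_adapter(
            seq, trim_config.ltr_adapter, trim_config.error_rate,
            end="5p", min_overlap=trim_config.min_overlap,
        )
        if ltr is not None:
            seq, qual = seq[ltr.stop:], qual[ltr.stop:]
        linker = find_adapter(
            seq, trim_config.linker_adapter, trim_config.error_rate,
            end="3p", min_overlap=trim_config.min_overlap,
        ) if seq else None
        if linker is not None:
            seq, qual = seq[: linker.start], qual[: linker.start]

        if ltr is None and linker is None:
            if trim_config.discard_untrimmed:
                log_rows.append((read.read_id, "untrimmed_discarded", len(seq)))
                continue
            action = "untrimmed_kept"
        else:
            action = "trimmed"
        if len(seq) < trim_config.min_read_len:
            log_rows.append((read.read_id, "too_short", len(seq)))
            continue
        log_rows.append((read.read_id, action, len(seq)))
        kept.append(ReadRecord(read.read_id, seq, qual))
    log = pd.DataFrame(log_rows, columns=["read_id", "action", "trimmed_length"])
    return kept, log


def read_fastq(path: str | Path) -> list[ReadRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq), qual))
    return out


def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    from .synthetic import write_fastq as _wf

    _wf(reads, path)
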