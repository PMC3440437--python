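"""Plain-text readers and writers for every pipeline artifact.

All formats are delimited text (CSV with ``# key=value`` metadata comment
lines) or JSON.  Channel and state indices are 1-based on disk, matching the
printed rule-table convention.  Every writer/reader pair round-trips
losslessly; readers raise :class:`ParseError` with the offending line number
on malformed input.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .core import (
    CountMatrix,
    DecoderOutput,
    SpikeTrainSet,
    StateSequence,
    Template,
    TemplateSet,
    counter_max,
)


class ParseError(ValueError):
    """Malformed input file; message includes path and line number."""


def _fail(path, lineno, msg):
    raise ParseError(f"{path}:{lineno}: {msg}")


def _read_lines(path):
    """Yield (lineno, row) for data rows; collect '# key=value' metadata."""
    meta = {}
    rows = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            rows.append((lineno, next(csv.reader([line]))))
    return meta, rows


def _meta_float(meta, key, path):
    try:
        return float(meta[key])
    except KeyError:
        raise ParseError(f"{path}: missing metadata '# {key}='")
    except ValueError:
        raise ParseError(f"{path}: metadata {key} is not a number")


def _meta_int(meta, key, path):
    return int(_meta_float(meta, key, path))


# ---------------------------------------------------------------- spike trains


def write_spike_trains(spikes: SpikeTrainSet, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# duration_s={spikes.duration!r}\n")
        fh.write(f"# channels={spikes.channel_count}\n")
        fh.write("channel,time_s\n")
        w = csv.writer(fh)
        for ch, times in enumerate(spikes.spikes, start=1):
            for t in times:
                w.writerow([ch, repr(float(t))])


def read_spike_trains(path) -> SpikeTrainSet:
    meta, rows = _read_lines(path)
    duration = _meta_float(meta, "duration_s", path)
    n = _meta_int(meta, "channels", path)
    per_channel: list[list[float]] = [[] for _ in range(n)]
    for lineno, row in rows:
        if row[0] == "channel":
            continue  # header
        if len(row) != 2:
            _fail(path, lineno, f"expected 2 fields, got {len(row)}")
        try:
            ch = int(row[0])
            t = float(row[1])
        except ValueError:
            _fail(path, lineno, f"cannot parse row {row!r}")
        if not 1 <= ch <= n:
            _fail(path, lineno, f"channel {ch} outside 1..{n}")
        per_channel[ch - 1].append(t)
    return SpikeTrainSet([np.array(c) for c in per_channel], duration)


# --------------------------------------------------------------- count matrix


def write_count_matrix(counts: CountMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# window_length_s={counts.window_length!r}\n")
        fh.write(f"# counter_bits={counts.counter_bits}\n")
        fh.write(f"# start_time_s={counts.start_time!r}\n")
        fh.write(",".join(f"ch{i + 1}" for i in range(counts.n_channels)) + "\n")
        w = csv.writer(fh)
        for row in counts.counts:
            w.writerow([int(v) for v in row])


def read_count_matrix(path) -> CountMatrix:
    meta, rows = _read_lines(path)
    W = _meta_float(meta, "window_length_s", path)
    bits = _meta_int(meta, "counter_bits", path)
    start = float(meta.get("start_time_s", 0.0))
    cmax = counter_max(bits)
    data = []
    ncol = None
    for lineno, row in rows:
        if row[0].startswith("ch"):
            ncol = len(row)
            continue
        try:
            vals = [int(v) for v in row]
        except ValueError:
            _fail(path, lineno, f"non-integer count in row {row!r}")
        if ncol is not None and len(vals) != ncol:
            _fail(path, lineno, f"expected {ncol} columns, got {len(vals)}")
        for v in vals:
            if not 0 <= v <= cmax:
                _fail(path, lineno, f"count {v} outside 0..{cmax} for b={bits}")
        data.append(vals)
    if not data:
        raise ParseError(f"{path}: no count rows")
    return CountMatrix(np.array(data, dtype=int), W, bits, start)


# ------------------------------------------------------------- state sequence


def write_state_sequence(seq: StateSequence, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# K={seq.K}\n")
        if seq.segment_length is not None:
            fh.write(f"# segment_length_m={seq.segment_length!r}\n")
        fh.write("window,state\n")
        w = csv.writer(fh)
        for i, s in enumerate(seq.states):
            w.writerow([i, int(s)])


def read_state_sequence(path) -> StateSequence:
    meta, rows = _read_lines(path)
    K = _meta_int(meta, "K", path)
    seg = float(meta["segment_length_m"]) if "segment_length_m" in meta else None
    states = []
    for lineno, row in rows:
        if row[0] == "window":
            continue
        if len(row) != 2:
            _fail(path, lineno, f"expected 2 fields, got {len(row)}")
        try:
            s = int(row[1])
        except ValueError:
            _fail(path, lineno, f"non-integer state {row[1]!r}")
        if not 0 <= s <= K:
            _fail(path, lineno, f"state {s} outside 0..{K}")
        states.append(s)
    return StateSequence(np.array(states, dtype=int), K, segment_length=seg)


# ----------------------------------------------------------------- rule table


def write_templates(templates: TemplateSet, path) -> None:
    """JSON rule table: the decoder's program, with 1-based indices."""
    doc = {
        "K": templates.K,
        "M": templates.M,
        "counter_bits": templates.counter_bits,
        "templates": [
            {
                "state": t.state,
                "entries": [[int(c), int(th)] for c, th in t.entries],
                "op": t.op,
            }
            for t in templates.templates
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_templates(path) -> TemplateSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}:{e.lineno}: invalid JSON ({e.msg})")
    try:
        tpls = [
            Template(
                state=int(t["state"]),
                entries=[(int(c), int(th)) for c, th in t["entries"]],
                op=t.get("op", "conjunction_at_least"),
            )
            for t in doc["templates"]
        ]
        return TemplateSet(int(doc["K"]), int(doc["M"]), int(doc["counter_bits"]), tpls)
    except (KeyError, TypeError, ValueError) as e:
        raise ParseError(f"{path}: malformed rule table ({e})")


def export_rule_table_csv(templates: TemplateSet, path) -> None:
    """Classic printed rule-table layout: one column per state, row pairs
    (c1, theta1, c2, theta2, ...), blanks where a state has fewer entries.

    A state with several templates exports its first; the JSON format is the
    lossless one.
    """
    cols: dict[int, list[tuple[int, int]]] = {}
    for t in templates.templates:
        cols.setdefault(t.state, t.entries)
    with open(path, "w", newline="") as fh:
        fh.write(f"# K={templates.K}\n")
        fh.write(f"# M={templates.M}\n")
        fh.write(f"# counter_bits={templates.counter_bits}\n")
        fh.write("row," + ",".join(str(k) for k in range(1, templates.K + 1)) + "\n")
        w = csv.writer(fh)
        for m in range(templates.M):
            crow, trow = [f"c{m + 1}"], [f"theta{m + 1}"]
            for k in range(1, templates.K + 1):
                entries = cols.get(k, [])
                if m < len(entries):
                    crow.append(str(entries[m][0]))
                    trow.append(str(entries[m][1]))
                else:
                    crow.append("")
                    trow.append("")
            w.writerow(crow)
            w.writerow(trow)


def read_rule_table_csv(path) -> TemplateSet:
    """Parse the printed-style rule table back into a TemplateSet."""
    meta, rows = _read_lines(path)
    K = _meta_int(meta, "K", path)
    M = _meta_int(meta, "M", path)
    bits = _meta_int(meta, "counter_bits", path)
    chan_rows: dict[int, list[str]] = {}
    thr_rows: dict[int, list[str]] = {}
    for lineno, row in rows:
        if row[0] == "row":
            continue
        tag = row[0]
        if len(row) != K + 1:
            _fail(path, lineno, f"expected {K + 1} fields, got {len(row)}")
        if tag.startswith("c"):
            chan_rows[int(tag[1:])] = row[1:]
        elif tag.startswith("theta"):
            thr_rows[int(tag[5:])] = row[1:]
        else:
            _fail(path, lineno, f"unrecognized row tag {tag!r}")
    templates = []
    for k in range(1, K + 1):
        entries = []
        for m in sorted(chan_rows):
            c, th = chan_rows[m][k - 1].strip(), thr_rows[m][k - 1].strip()
            if c and th:
                entries.append((int(c), int(th)))
        if entries:
            templates.append(Template(state=k, entries=entries))
    return TemplateSet(K, M, bits, templates)


# ------------------------------------------------------------- decoder output


def write_decoder_output(output: DecoderOutput, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# window_length_s={output.window_length!r}\n")
        fh.write(",".join(f"s{k + 1}" for k in range(output.K)) + "\n")
        w = csv.writer(fh)
        for row in output.bits:
            w.writerow([int(v) for v in row])


def read_decoder_output(path) -> DecoderOutput:
    meta, rows = _read_lines(path)
    W = _meta_float(meta, "window_length_s", path)
    data = []
    for lineno, row in rows:
        if row[0].startswith("s") and not row[0].isdigit():
            continue
        try:
            vals = [int(v) for v in row]
        except ValueError:
            _fail(path, lineno, f"non-integer bit in row {row!r}")
        if any(v not in (0, 1) for v in vals):
            _fail(path, lineno, "decoder output bits must be 0 or 1")
        data.append(vals)
    if not data:
        raise ParseError(f"{path}: no output rows")
    return DecoderOutput(np.array(data, dtype=np.uint8), W)
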