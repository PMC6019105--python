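"""Trial-log files: commented header plus a tab-separated body.

The on-disk format mirrors the serial-monitor stream the firmware would
emit: `#`-prefixed header lines carry the trial metadata as ``key=json``
pairs, then a tab-separated table with one row per acquisition cycle:

    t_s  mode  stage  target_v_cms  pwm1  pwm2  pulses1  pulses2
    f1_mls  f2_mls  velocity_cms  temp_c  kill

Floats are written with ``repr`` so a write/read round trip is the
identity; the header records the body row count, which the reader checks so
truncated files fail with the offending line number.
"""

from __future__ import annotations

import json

from .controller import AcquisitionRecord, TrialLog

__all__ = ["COLUMNS", "LogFormatError", "write_log", "read_log"]

COLUMNS = ("t_s", "mode", "stage", "target_v_cms", "pwm1", "pwm2",
           "pulses1", "pulses2", "f1_mls", "f2_mls", "velocity_cms",
           "temp_c", "kill")


class LogFormatError(ValueError):
    """Malformed trial-log file (carries the offending line number)."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_log(log: TrialLog, path, timestamp: str | None = None) -> None:
    """Write a :class:`TrialLog` to ``path``.

    ``timestamp`` (an ISO string) is recorded in the header if given;
    omitting it keeps output byte-identical across runs.
    """
    lines = []
    if timestamp is not None:
        lines.append(f"# timestamp={json.dumps(timestamp)}")
    lines.append(f"# n_records={len(log.records)}")
    for key in sorted(log.meta):
        lines.append(f"# {key}={json.dumps(log.meta[key])}")
    lines.append("\t".join(COLUMNS))
    for r in log.records:
        row = (r.t, r.mode, r.stage_index, r.target_v, r.pwm1, r.pwm2,
               r.pulses1, r.pulses2, r.f1, r.f2, r.velocity, r.temp,
               int(r.kill))
        lines.append("\t".join(_fmt(v) for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_log(path) -> TrialLog:
    """Read a trial-log file back into a :class:`TrialLog` (lossless)."""
    meta: dict = {}
    n_expected: int | None = None
    records: list[AcquisitionRecord] = []
    header_seen = False
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if header_seen:
                    raise LogFormatError("header line after the body began", line_no)
                body = line[1:].strip()
                if "=" not in body:
                    raise LogFormatError(f"malformed header line {body!r}", line_no)
                key, _, val = body.partition("=")
                try:
                    val = json.loads(val)
                except json.JSONDecodeError as exc:
                    raise LogFormatError(f"bad header value for {key!r}: {exc}", line_no)
                if key.strip() == "n_records":
                    n_expected = int(val)
                elif key.strip() != "timestamp":
                    meta[key.strip()] = val
                continue
            if not header_seen:
                header_seen = True
                if line.split("\t") != list(COLUMNS):
                    raise LogFormatError("unexpected column header", line_no)
                continue
            fields = line.split("\t")
            if len(fields) != len(COLUMNS):
                raise LogFormatError(
                    f"expected {len(COLUMNS)} columns, found {len(fields)}", line_no)
            try:
                rec = AcquisitionRecord(
                    t=float(fields[0]), mode=fields[1], stage_index=int(fields[2]),
                    target_v=float(fields[3]), pwm1=int(fields[4]),
                    pwm2=int(fields[5]), pulses1=int(fields[6]),
                    pulses2=int(fields[7]), f1=float(fields[8]),
                    f2=float(fields[9]), velocity=float(fields[10]),
                    temp=float(fields[11]), kill=bool(int(fields[12])))
            except ValueError as exc:
                raise LogFormatError(str(exc), line_no)
            records.append(rec)
    if not header_seen:
        raise LogFormatError("no column header found", line_no=None)
    if n_expected is not None and len(records) != n_expected:
        raise LogFormatError(
            f"truncated file: header promises {n_expected} records, found "
            f"{len(records)}", line_no=line_no)
    return TrialLog(meta=meta, records=records)
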