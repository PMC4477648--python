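"""Tabular output (TSV with '#' config-echo headers, BED6) and re-readers."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .scanner import PQSHit, chromosome_code, make_id

__all__ = [
    "assign_ids",
    "hits_to_frame",
    "slqs_to_frame",
    "rejections_to_frame",
    "write_tsv",
    "write_bed6",
    "read_hits_tsv",
    "SimpleHit",
]


def assign_ids(hits) -> list[str]:
    """G4ST-style IDs where the sequence is a codeable chromosome, otherwise
    '<name>|<1-based pos>|<k>' (k disambiguates same-start placements)."""
    ids = []
    seen: dict[tuple, int] = {}
    for hit in hits:
        pos = hit.span[0] + 1
        try:
            base = make_id(hit, chromosome_code(hit.seq_name), pos)
        except ValueError:
            base = f"{hit.seq_name}|{pos}"
        k = seen.get((base,), 0)
        seen[(base,)] = k + 1
        ids.append(base if k == 0 else f"{base}|{k}")
    return ids


def _hit_row(hit: PQSHit, hid: str, seq: str) -> dict:
    return {
        "id": hid,
        "seq_name": hit.seq_name,
        "strand": hit.strand,
        "start_0based": hit.span[0],
        "end": hit.span[1],
        "class": hit.class_label,
        "L1": hit.loop_lengths[0],
        "L2": hit.loop_lengths[1],
        "L3": hit.loop_lengths[2],
        "tract_lengths": ",".join(str(t) for t in hit.tract_lengths),
        "sequence": hit.sequence(seq),
    }


def hits_to_frame(hits, record, ids=None) -> pd.DataFrame:
    ids = ids if ids is not None else assign_ids(hits)
    return pd.DataFrame([_hit_row(h, i, record.seq) for h, i in zip(hits, ids)])


def slqs_to_frame(slqs_records, record, ids=None) -> pd.DataFrame:
    hits = [r.hit for r in slqs_records]
    ids = ids if ids is not None else assign_ids(hits)
    rows = []
    for rec, hid in zip(slqs_records, ids):
        row = _hit_row(rec.hit, hid, record.seq)
        row["class"] = "SLQS"
        row["n_stemloops"] = rec.n_stemloops
        row["loop_raw"] = ",".join(l.raw_seq for l in rec.loops)
        row["loop_ext"] = ",".join(l.ext_seq for l in rec.loops)
        row["dot_bracket"] = ",".join(rec.dot_brackets)
        row["dG37"] = ",".join(f"{p.dG37:.2f}" for p in rec.predictions)
        rows.append(row)
    return pd.DataFrame(rows)


def rejections_to_frame(rejections, record, ids=None) -> pd.DataFrame:
    hits = [r.hit for r in rejections]
    ids = ids if ids is not None else assign_ids(hits)
    rows = []
    for rej, hid in zip(rejections, ids):
        row = _hit_row(rej.hit, hid, record.seq)
        row["class"] = "REJECTED"
        row["failed_loop"] = rej.loop_index
        row["reasons"] = "; ".join(rej.reasons)
        rows.append(row)
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_bed6(hits, ids, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for hit, hid in zip(hits, ids):
            fh.write(
                f"{hit.seq_name}\t{hit.span[0]}\t{hit.span[1]}\t{hid}\t0\t{hit.strand}\n"
            )


@dataclass(frozen=True)
class SimpleHit:
    """Light hit view reconstructed from a scan TSV (for annotation steps)."""

    seq_name: str
    strand: str
    span: tuple[int, int]
    class_label: str
    id: str
    tracts: tuple[tuple[int, int], ...] = ()


def read_hits_tsv(path) -> list[SimpleHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        SimpleHit(
            seq_name=str(sn), strand=str(st), span=(int(s), int(e)),
            class_label=str(cl), id=str(hid),
        )
        for sn, st, s, e, cl, hid in zip(
            df["seq_name"], df["strand"], df["start_0based"], df["end"],
            df["class"], df["id"],
        )
    ]
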