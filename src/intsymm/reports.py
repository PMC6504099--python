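"""Writers for user-facing outputs: summary TSV, gapped repeat FASTA, axes
TSV and result JSON.  All files are UTF-8 text with LF line endings; residue
ranges use author numbering."""

from __future__ import annotations

import json
import logging

from .engine import SymmetryResult, result_to_dict
from .optimize import GAP
from .params import EngineParams
from .structure_io import one_letter

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "id", "significant", "overall_label", "total_order", "levels",
    "tm_self", "tm_avg", "rmsd", "coverage", "repeat_ranges",
]


def _range_str(result: SymmetryResult, start: int, end: int) -> str:
    lab_s = result.trace.labels[start]
    lab_e = result.trace.labels[end]
    chain = getattr(lab_s, "chain", "A")
    num_s = getattr(lab_s, "number", start)
    num_e = getattr(lab_e, "number", end)
    return f"{chain}_{num_s}-{num_e}"


def tsv_row(result: SymmetryResult) -> str:
    ranges = ";".join(_range_str(result, s, e) for s, e in result.repeat_ranges())
    levels = ";".join(lv.label for lv in result.levels) or "C1"
    fields = [
        result.source_id,
        str(result.significant).lower(),
        result.overall_label,
        str(result.total_order),
        levels,
        f"{result.tm_self:.4f}",
        f"{result.tm_avg:.4f}",
        f"{result.rmsd:.4f}",
        f"{result.coverage:.4f}",
        ranges,
    ]
    return "\t".join(fields)


def write_tsv(results: list, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for result in results:
            fh.write(tsv_row(result) + "\n")


def write_fasta_repeats(result: SymmetryResult, path, append: bool = False) -> bool:
    """One gapped FASTA record per repeat of a significant result.

    Record ids are "<id>_<chain>_<start>-<end>" in author numbering; all
    records have equal length.  Returns False (and writes nothing) for a
    non-significant result.
    """
    if not result.significant or result.alignment is None:
        logger.warning("no repeats to write for %s (not significant)", result.source_id)
        return False
    aln = result.alignment
    with open(path, "a" if append else "w", encoding="utf-8", newline="\n") as fh:
        for r in range(aln.n_repeats):
            row = aln.matrix[r]
            pos = row[row != GAP]
            rid = f"{result.source_id}_{_range_str(result, int(pos[0]), int(pos[-1]))}"
            seq = "".join(
                "-" if row[c] == GAP else one_letter(
                    getattr(result.trace.labels[row[c]], "name", "X")
                )
                for c in range(aln.n_columns)
            )
            fh.write(f">{rid}\n{seq}\n")
    return True


AXES_COLUMNS = [
    "id", "level", "label", "theta_deg", "screw_A",
    "axis_point", "axis_dir", "repeat_ranges",
]


def write_axes(results: list, path) -> None:
    """One row per symmetry axis: level, label token, rotation angle, screw
    translation, a point on the axis, its direction, and the repeat ranges
    it relates."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(AXES_COLUMNS) + "\n")
        for result in results:
            for i, lv in enumerate(result.levels, start=1):
                from .refine import repeat_ranges as _rr

                ranges = ";".join(
                    _range_str(result, s, e) for s, e in _rr(lv.alignment)
                )
                point = ",".join(f"{x:.3f}" for x in lv.axis.point)
                direc = ",".join(f"{x:.4f}" for x in lv.axis.direction)
                fh.write(
                    f"{result.source_id}\t{i}\t{lv.label}\t{lv.axis.theta_deg:.3f}\t"
                    f"{lv.axis.screw_t:.3f}\t{point}\t{direc}\t{ranges}\n"
                )


def write_json(results: list, params: EngineParams, path) -> None:
    payload = [result_to_dict(r, params) for r in results]
    if len(payload) == 1:
        payload = payload[0]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
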