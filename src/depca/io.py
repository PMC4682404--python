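"""Tab-delimited readers and writers.

All files are UTF-8 TSV with a single header line; axis-model files add
``#`` metadata lines.  Numbers are written with ``%.12g`` so that shared
axis files reproduce bit-exactly across platforms at that precision.
Missing values are written as ``NA``; on input both ``NA`` and an empty
field mean missing.

Expression matrices are item-by-sample on disk (the series-matrix
convention); the transpose to the internal sample-by-item orientation
happens exactly once, inside :func:`depca.core.center`.
"""

from __future__ import annotations

import logging
from pathlib import Path
import numpy as np
import pandas as pd

from . import core
from .core import (AxisModel, ComponentTable, Design, ExpressionMatrix,
                   ReferenceVector)
from .errors import DataError, UsageError
from .filtering import FilterResult, ProbeLevelData

logger = logging.getLogger(__name__)

PRECISION = "%.12g"
_MODEL_MAGIC = "# depca-axis-model v1"


def _fmt(x: float) -> str:
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    return PRECISION % x


def _parse_cell(cell: str, path: str, lineno: int, col: str) -> float:
    cell = cell.strip()
    if cell in ("", "NA"):
        return np.nan
    try:
        return float(cell)
    except ValueError:
        raise DataError(
            f"{path}:{lineno}: non-numeric value {cell!r} in column {col!r}"
        ) from None


def _read_tsv_grid(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Parse a row-id + header TSV grid, reporting problems by line number."""
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise DataError(f"{path}:1: empty file or missing header")
        header = header_line.split("\t")
        col_ids = header[1:]
        if len(set(col_ids)) != len(col_ids):
            raise DataError(f"{path}:1: duplicate column ids")
        row_ids: list[str] = []
        seen: set[str] = set()
        data: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise DataError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}")
            rid = fields[0]
            if rid in seen:
                raise DataError(f"{path}:{lineno}: duplicate row id {rid!r}")
            seen.add(rid)
            row_ids.append(rid)
            data.append([_parse_cell(c, path, lineno, col_ids[j])
                         for j, c in enumerate(fields[1:])])
    return row_ids, col_ids, np.asarray(data, dtype=float)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an item-by-sample TSV (first column item_id, NA/empty missing)."""
    item_ids, sample_ids, values = _read_tsv_grid(path)
    if not item_ids:
        raise DataError(f"{path}: no data rows")
    return ExpressionMatrix(values=pd.DataFrame(
        values, index=item_ids, columns=sample_ids))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("item_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for item, row in zip(matrix.item_ids, matrix.values.to_numpy()):
            fh.write(item + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def read_design(path: str | Path,
                reference_rule: str | None = None,
                control_label: str | None = None) -> Design:
    """Read a sample_id/group table, optional is_reference flag column.

    A truthy ``is_reference`` flag marks the control group's samples; all
    flagged samples must share one group.  An explicit ``reference_rule``
    argument overrides the file.
    """
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_sample = header.index("sample_id")
            i_group = header.index("group")
        except ValueError:
            raise DataError(
                f"{path}:1: header must contain sample_id and group") from None
        i_ref = header.index("is_reference") if "is_reference" in header else None
        group_of: dict[str, str] = {}
        flagged_groups: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise DataError(f"{path}:{lineno}: expected {len(header)} "
                                f"fields, got {len(fields)}")
            sid, group = fields[i_sample], fields[i_group]
            if sid in group_of:
                raise DataError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            group_of[sid] = group
            if i_ref is not None:
                flag = fields[i_ref].strip().lower()
                if flag in _TRUTHY:
                    flagged_groups.add(group)
                elif flag not in _FALSY:
                    raise DataError(
                        f"{path}:{lineno}: bad is_reference value {flag!r}")
    if not group_of:
        raise DataError(f"{path}: no samples")
    if reference_rule is None:
        if flagged_groups:
            if len(flagged_groups) > 1:
                raise DataError(
                    f"{path}: is_reference flags span several groups: "
                    f"{sorted(flagged_groups)}")
            reference_rule = core.CONTROL_GROUP
            control_label = next(iter(flagged_groups))
        else:
            reference_rule = core.GRAND_MEAN
    return Design(group_of=group_of, reference_rule=reference_rule,
                  control_label=control_label)


def write_design(design: Design, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tis_reference\n")
        for sid, group in design.group_of.items():
            flag = "1" if (design.reference_rule == core.CONTROL_GROUP
                           and group == design.control_label) else "0"
            fh.write(f"{sid}\t{group}\t{flag}\n")


# ---------------------------------------------------------------------------
# axis-model container
# ---------------------------------------------------------------------------

def save_axis_model(model: AxisModel, path: str | Path) -> None:
    """Write the shareable container: metadata, then the singular values,
    reference vector, loadings and (when present) left-vector blocks."""
    labels = model.axis_labels
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MODEL_MAGIC + "\n")
        fh.write(f"# n_t: {model.n_t}\n")
        fh.write(f"# m_f: {model.m_f}\n")
        fh.write(f"# n_axes: {model.n_axes}\n")
        fh.write(f"# sign_convention: {model.sign_convention}\n")
        fh.write(f"# reference_rule: {model.reference.provenance}\n")
        fh.write("# block: singular_values\n")
        fh.write("axis\tsigma\n")
        for lab, s in zip(labels, model.d):
            fh.write(f"{lab}\t{_fmt(s)}\n")
        fh.write("# block: reference\n")
        fh.write("item_id\treference\texcluded\n")
        undef = model.reference.undefined_items
        for item, r in model.reference.r.items():
            fh.write(f"{item}\t{_fmt(r)}\t{1 if item in undef else 0}\n")
        fh.write("# block: loadings\n")
        fh.write("item_id\t" + "\t".join(labels) + "\n")
        for item, row in zip(model.item_ids, model.V.to_numpy()):
            fh.write(item + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
        if model.U is not None:
            fh.write("# block: left_vectors\n")
            fh.write("row\t" + "\t".join(labels) + "\n")
            for rid, row in zip(model.U.index, model.U.to_numpy()):
                fh.write(str(rid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def _split_blocks(lines: list[str], path: str) -> tuple[dict[str, str],
                                                        dict[str, list[str]]]:
    meta: dict[str, str] = {}
    blocks: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in lines:
        if line.startswith("# block:"):
            name = line.split(":", 1)[1].strip()
            if name in blocks:
                raise DataError(f"{path}: duplicate block {name!r}")
            current = blocks.setdefault(name, [])
        elif line.startswith("#"):
            if ":" in line:
                key, val = line[1:].split(":", 1)
                meta[key.strip()] = val.strip()
        elif line.strip():
            if current is None:
                raise DataError(f"{path}: data before any block header")
            current.append(line)
    return meta, blocks


def load_axis_model(path: str | Path) -> AxisModel:
    """Read a shared axis-model file, checking internal consistency."""
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != _MODEL_MAGIC:
            raise DataError(f"{path}: not an axis-model file "
                            f"(expected {_MODEL_MAGIC!r})")
        lines = [ln.rstrip("\n") for ln in fh]
    meta, blocks = _split_blocks(lines, path)
    for key in ("n_t", "m_f", "n_axes"):
        if key not in meta:
            raise DataError(f"{path}: missing metadata line '# {key}:'")
    n_t, m_f, n_axes = (int(meta[k]) for k in ("n_t", "m_f", "n_axes"))
    for name in ("singular_values", "reference", "loadings"):
        if name not in blocks:
            raise DataError(f"{path}: missing block {name!r}")

    sv_rows = [ln.split("\t") for ln in blocks["singular_values"][1:]]
    d = np.array([float(r[1]) for r in sv_rows])
    if len(d) != n_axes:
        raise DataError(f"{path}: singular_values block has {len(d)} rows "
                        f"but n_axes is {n_axes}")

    ref_rows = [ln.split("\t") for ln in blocks["reference"][1:]]
    ref = pd.Series({r[0]: float(r[1]) for r in ref_rows})
    undefined = frozenset(r[0] for r in ref_rows if r[2] == "1")

    header = blocks["loadings"][0].split("\t")
    if len(header) - 1 != n_axes:
        raise DataError(f"{path}: loadings block has {len(header) - 1} axis "
                        f"columns but n_axes is {n_axes}")
    load_rows = [ln.split("\t") for ln in blocks["loadings"][1:]]
    items = [r[0] for r in load_rows]
    V = np.array([[float(v) for v in r[1:]] for r in load_rows])
    if len(items) != len(ref):
        raise DataError(f"{path}: loadings block has {len(items)} items but "
                        f"reference block has {len(ref)}")
    if m_f > len(items) or m_f < 1:
        raise DataError(f"{path}: m_f = {m_f} inconsistent with "
                        f"{len(items)} loading rows")
    labels = header[1:]

    U = None
    if "left_vectors" in blocks:
        u_rows = [ln.split("\t") for ln in blocks["left_vectors"][1:]]
        if len(u_rows) != n_t:
            raise DataError(f"{path}: left_vectors block has {len(u_rows)} "
                            f"rows but n_t is {n_t}")
        U = pd.DataFrame([[float(v) for v in r[1:]] for r in u_rows],
                         index=[r[0] for r in u_rows], columns=labels)

    model = AxisModel(
        V=pd.DataFrame(V, index=items, columns=labels),
        d=d,
        reference=ReferenceVector(r=ref.reindex(items),
                                  provenance=meta.get("reference_rule", "unknown"),
                                  undefined_items=undefined),
        n_t=n_t, m_f=m_f, U=U,
        sign_convention=meta.get("sign_convention", core.SIGN_CONVENTION),
    )
    model.validate(atol=1e-8)  # text round-trip precision
    return model


# ---------------------------------------------------------------------------
# component tables
# ---------------------------------------------------------------------------

def write_component_table(table: ComponentTable | pd.DataFrame,
                          path: str | Path) -> None:
    """Write scores as id, row_kind, then one column per axis."""
    if isinstance(table, ComponentTable):
        frame = table.scores.copy()
        frame.insert(0, "row_kind", "sample" if table.row_kind == "samples"
                     else "item")
    else:
        frame = table
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(map(str, frame.columns)) + "\n")
        for rid, row in frame.iterrows():
            cells = [v if isinstance(v, str) else _fmt(v) for v in row]
            fh.write(str(rid) + "\t" + "\t".join(cells) + "\n")


def joint_component_table(sample_scores: ComponentTable,
                          item_scores: ComponentTable) -> pd.DataFrame:
    """Biplot-like joint table: samples and items on identical scaled axes.

    Unlike a classical biplot, which splits the magnitude between the two
    factors, scaled sample and item scores carry the full magnitude and
    share one size unit, so they can be listed (or plotted) together.
    """
    if not (sample_scores.scaled and item_scores.scaled):
        raise UsageError("joint table requires scaled component tables")
    if sample_scores.row_kind != "samples" or item_scores.row_kind != "items":
        raise UsageError("expected a sample table and an item table")
    if list(sample_scores.scores.columns) != list(item_scores.scores.columns):
        raise DataError("component tables disagree on axis columns; "
                        "were they produced by the same axis model?")
    s = sample_scores.scores.copy()
    s.insert(0, "row_kind", "sample")
    i = item_scores.scores.copy()
    i.insert(0, "row_kind", "item")
    return pd.concat([s, i], axis=0)


# ---------------------------------------------------------------------------
# probe-level data and filter results
# ---------------------------------------------------------------------------

def read_probe_level(path: str | Path) -> ProbeLevelData:
    """Read gene_id, probe_id, then sample columns."""
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "probe_id"]:
            raise DataError(f"{path}:1: header must start with gene_id, probe_id")
        samples = header[2:]
        tuples, data = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise DataError(f"{path}:{lineno}: expected {len(header)} "
                                f"fields, got {len(fields)}")
            tuples.append((fields[0], fields[1]))
            data.append([_parse_cell(c, path, lineno, samples[j])
                         for j, c in enumerate(fields[2:])])
    index = pd.MultiIndex.from_tuples(tuples, names=["gene_id", "probe_id"])
    return ProbeLevelData(values=pd.DataFrame(np.asarray(data), index=index,
                                              columns=samples))


def write_probe_level(data: ProbeLevelData, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tprobe_id\t" + "\t".join(data.sample_ids) + "\n")
        for (gene, probe), row in zip(data.values.index,
                                      data.values.to_numpy()):
            fh.write(f"{gene}\t{probe}\t"
                     + "\t".join(_fmt(v) for v in row) + "\n")


def write_filter_result(result: FilterResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tp_value\tpositive\tuntestable\n")
        for gene, row in result.table.iterrows():
            fh.write(f"{gene}\t{_fmt(row['p_value'])}\t"
                     f"{int(row['positive'])}\t{int(row['untestable'])}\n")


def read_filter_result(path: str | Path, alpha: float = 0.01) -> FilterResult:
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "gene_id":
            raise DataError(f"{path}:1: expected gene_id header")
        rows = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 fields")
            rows[f[0]] = (_parse_cell(f[1], path, lineno, "p_value"),
                          bool(int(f[2])), bool(int(f[3])))
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["p_value", "positive", "untestable"])
    return FilterResult(table=table, alpha=alpha)
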