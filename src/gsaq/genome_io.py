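"""Readers, writers and domain containers for gene annotations, QTL tables,
gene sets and two-class expression matrices.

Coordinate convention
---------------------
All internal coordinates are 1-based and closed on both ends, the convention
used by GFF and by the Gramene QTL database.  BED input (0-based, half-open)
is converted on read: ``start + 1, end``.  Containment tests elsewhere in the
package rely on this being applied uniformly.

Chromosome names are compared as exact strings after trimming whitespace; no
silent "chr"-prefix coercion is performed (see :func:`normalize_chrom_names`
for the explicit, symmetric option).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "Qtl",
    "GeneSpace",
    "QtlSet",
    "GeneSet",
    "ExpressionMatrix",
    "read_gene_annotation",
    "read_qtl_table",
    "read_gene_set",
    "read_expression",
    "write_gene_annotation",
    "write_qtl_table",
    "write_gene_set",
    "write_expression",
    "write_report",
    "normalize_chrom_names",
]


@dataclass(frozen=True)
class Gene:
    """A gene interval g[a, b] on a chromosome, 1-based closed."""

    gene_id: str
    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be nonempty")
        if self.start < 1:
            raise ValidationError(
                f"gene {self.gene_id}: start must be >= 1, got {self.start}"
            )
        if self.stop < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: stop {self.stop} < start {self.start}"
            )


@dataclass(frozen=True)
class Qtl:
    """A trait-labelled QTL interval q[d, e] on a chromosome, 1-based closed."""

    qtl_id: str
    trait: str
    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not self.qtl_id:
            raise ValidationError("qtl_id must be nonempty")
        if self.start < 1:
            raise ValidationError(
                f"QTL {self.qtl_id}: start must be >= 1, got {self.start}"
            )
        if self.stop < self.start:
            raise ValidationError(
                f"QTL {self.qtl_id}: stop {self.stop} < start {self.start}"
            )


class GeneSpace:
    """The whole annotated gene space Omega: an ordered collection of genes,
    unique by gene_id.

    ``N`` is the number of genes; membership and coordinate lookups are O(1).
    """

    def __init__(self, genes: Iterable[Gene]):
        self.genes: tuple[Gene, ...] = tuple(genes)
        index: dict[str, int] = {}
        for i, g in enumerate(self.genes):
            if g.gene_id in index:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            index[g.gene_id] = i
        self._index = index

    @property
    def N(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[self._index[gene_id]]

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chrom, None)
        return list(seen)

    def __repr__(self) -> str:
        return f"GeneSpace(N={self.N}, chroms={len(self.chromosomes())})"


class QtlSet:
    """An ordered collection of QTLs for one trait (or trait='mixed')."""

    def __init__(self, qtls: Iterable[Qtl], trait: str | None = None):
        self.qtls: tuple[Qtl, ...] = tuple(qtls)
        seen: set[str] = set()
        for q in self.qtls:
            if q.qtl_id in seen:
                raise ValidationError(f"duplicate qtl_id {q.qtl_id!r}")
            seen.add(q.qtl_id)
        traits = {q.trait for q in self.qtls}
        if trait is None:
            trait = traits.pop() if len(traits) == 1 else "mixed"
        elif trait != "mixed" and traits - {trait}:
            raise ValidationError(
                f"QTLs carry traits {sorted(traits)} but declared trait is {trait!r}"
            )
        self.trait = trait

    def __len__(self) -> int:
        return len(self.qtls)

    def __iter__(self):
        return iter(self.qtls)

    @property
    def qtl_ids(self) -> tuple[str, ...]:
        return tuple(q.qtl_id for q in self.qtls)

    def __repr__(self) -> str:
        return f"QtlSet(|Q|={len(self.qtls)}, trait={self.trait!r})"


class GeneSet:
    """A selected gene set G: an ordered set of gene ids, ``n = |G|``.

    The complement G' = Omega - G is always derived from a parent
    :class:`GeneSpace`, never stored.
    """

    def __init__(self, member_ids: Iterable[str], space: GeneSpace | None = None):
        ordered: dict[str, None] = {}
        for gid in member_ids:
            ordered.setdefault(gid, None)
        self.member_ids: tuple[str, ...] = tuple(ordered)
        if not self.member_ids:
            raise ValidationError("gene set is empty")
        if space is not None:
            missing = [g for g in self.member_ids if g not in space]
            if missing:
                raise ValidationError(
                    f"{len(missing)} gene set member(s) absent from gene space, "
                    f"e.g. {missing[:3]}"
                )

    @property
    def n(self) -> int:
        return len(self.member_ids)

    def __len__(self) -> int:
        return len(self.member_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.member_ids)

    def __iter__(self):
        return iter(self.member_ids)

    def complement_ids(self, space: GeneSpace) -> tuple[str, ...]:
        members = set(self.member_ids)
        return tuple(g for g in space.gene_ids if g not in members)

    def __repr__(self) -> str:
        return f"GeneSet(n={self.n})"


@dataclass
class ExpressionMatrix:
    """Two-class expression matrix (genes x samples) on log2 scale.

    ``class_labels`` holds one of exactly two labels per sample.  Which label
    plays the role of "case" is immaterial to the filters and rankers, all of
    which are symmetric in the two classes (absolute differences and
    correlations).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    class_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.class_labels) != len(self.sample_ids):
            raise ValidationError("one class label required per sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids in expression matrix")
        if len(set(self.class_labels)) != 2:
            raise ValidationError(
                f"exactly two classes required, got {sorted(set(self.class_labels))}"
            )

    @property
    def classes(self) -> tuple[str, str]:
        return tuple(sorted(set(self.class_labels)))  # type: ignore[return-value]

    def class_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean sample masks for (first, second) class in sorted label order."""
        labels = np.asarray(self.class_labels)
        c0, c1 = self.classes
        return labels == c0, labels == c1

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(
            tuple(gene_ids), self.sample_ids, self.class_labels, self.values[rows]
        )


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_gene_annotation(path, format: str = "tsv") -> GeneSpace:
    """Read a gene annotation table into a :class:`GeneSpace`.

    ``format='bed'`` expects BED4 (chrom, start, end, name; 0-based half-open,
    converted to 1-based closed).  ``format='tsv'`` expects a headered table
    with columns gene_id, chrom, start, stop already in 1-based closed
    coordinates.  Rows with missing coordinates are skipped with a logged
    warning; duplicate gene ids raise.
    """
    if format not in ("bed", "tsv"):
        raise ValidationError(f"unknown gene annotation format {format!r}")
    if format == "bed":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                comment="#",
                names=["chrom", "start", "end", "gene_id"],
                usecols=[0, 1, 2, 3],
                dtype={"chrom": str, "gene_id": str},
            )
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"{path}: could not parse BED: {exc}") from exc
        df = df.rename(columns={"end": "stop"})
        coord_shift = 1  # BED start is 0-based
    else:
        try:
            df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
        except Exception as exc:  # pragma: no cover
            raise ParseError(f"{path}: could not parse TSV: {exc}") from exc
        _require_columns(df, ["gene_id", "chrom", "start", "stop"], path)
        df["chrom"] = df["chrom"].astype(str)
        coord_shift = 0

    genes: list[Gene] = []
    n_skipped = 0
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        if pd.isna(row.start) or pd.isna(row.stop) or pd.isna(row.gene_id):
            n_skipped += 1
            continue
        try:
            start = int(row.start) + coord_shift
            stop = int(row.stop)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: line {lineno}: non-integer coordinate "
                f"({row.start!r}, {row.stop!r})"
            ) from exc
        genes.append(Gene(str(row.gene_id), str(row.chrom).strip(), start, stop))
    if n_skipped:
        logger.warning(
            "%s: skipped %d row(s) with missing coordinates", path, n_skipped
        )
    return GeneSpace(genes)


def read_qtl_table(path) -> QtlSet:
    """Read a Gramene-style QTL table (TSV: qtl_id, trait, chrom, start, stop;
    1-based closed coordinates)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: QTL table is empty") from exc
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: could not parse TSV: {exc}") from exc
    if df.empty:
        raise ValidationError(f"{path}: QTL table has no rows")
    _require_columns(df, ["qtl_id", "trait", "chrom", "start", "stop"], path)
    qtls = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, stop = int(row.start), int(row.stop)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: line {lineno}: non-integer coordinate "
                f"({row.start!r}, {row.stop!r})"
            ) from exc
        if stop < start:
            raise ValidationError(
                f"{path}: line {lineno}: QTL {row.qtl_id} has stop < start"
            )
        qtls.append(
            Qtl(str(row.qtl_id), str(row.trait), str(row.chrom).strip(), start, stop)
        )
    return QtlSet(qtls)


def read_gene_set(path, space: GeneSpace) -> GeneSet:
    """Read a newline-delimited gene id list, resolving against ``space``.

    Ids absent from the space are dropped with a logged warning; duplicates
    are collapsed keeping first occurrence.  Zero resolvable ids raise.
    """
    with open(path) as fh:
        raw = [line.strip() for line in fh if line.strip()]
    resolved = [g for g in raw if g in space]
    n_dropped = len(set(raw) - set(resolved))
    if n_dropped:
        logger.warning("%s: dropped %d id(s) absent from gene space", path, n_dropped)
    if not resolved:
        raise ValidationError(f"{path}: no gene set ids resolve against the gene space")
    return GeneSet(resolved, space)


def read_expression(expr_path, classes_path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene_id, header = sample ids)
    plus a two-column sample-to-class TSV."""
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    cls = pd.read_csv(classes_path, sep="\t", dtype=str)
    if cls.shape[1] < 2:
        raise ParseError(f"{classes_path}: expected two columns (sample, class)")
    mapping = dict(zip(cls.iloc[:, 0], cls.iloc[:, 1]))
    missing = [s for s in df.columns if s not in mapping]
    if missing:
        raise ValidationError(
            f"{classes_path}: no class label for sample(s) {missing[:5]}"
        )
    return ExpressionMatrix(
        tuple(str(g) for g in df.index),
        tuple(str(s) for s in df.columns),
        tuple(mapping[s] for s in df.columns),
        df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# writers


def write_gene_annotation(space: GeneSpace, path, format: str = "tsv") -> None:
    if format == "bed":
        df = pd.DataFrame(
            [(g.chrom, g.start - 1, g.stop, g.gene_id) for g in space],
            columns=["chrom", "start", "end", "gene_id"],
        )
        df.to_csv(path, sep="\t", header=False, index=False)
    elif format == "tsv":
        df = pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.stop) for g in space],
            columns=["gene_id", "chrom", "start", "stop"],
        )
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown gene annotation format {format!r}")


def write_qtl_table(qtls: QtlSet, path) -> None:
    df = pd.DataFrame(
        [(q.qtl_id, q.trait, q.chrom, q.start, q.stop) for q in qtls],
        columns=["qtl_id", "trait", "chrom", "start", "stop"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for gid in gene_set:
            fh.write(gid + "\n")


def write_expression(expr: ExpressionMatrix, expr_path, classes_path) -> None:
    df = pd.DataFrame(expr.values, index=list(expr.gene_ids), columns=list(expr.sample_ids))
    df.index.name = "gene_id"
    df.to_csv(expr_path, sep="\t", float_format="%.10g")
    pd.DataFrame(
        {"sample": list(expr.sample_ids), "class": list(expr.class_labels)}
    ).to_csv(classes_path, sep="\t", index=False)


def normalize_chrom_names(strip_prefix: bool = True, *objs):
    """Symmetrically strip (or add) the 'chr' prefix on every Gene/Qtl of the
    given GeneSpace/QtlSet objects; returns new objects in input order."""
    out = []
    for obj in objs:
        if isinstance(obj, GeneSpace):
            out.append(GeneSpace(replace(g, chrom=_norm(g.chrom, strip_prefix)) for g in obj))
        elif isinstance(obj, QtlSet):
            out.append(
                QtlSet((replace(q, chrom=_norm(q.chrom, strip_prefix)) for q in obj), obj.trait)
            )
        else:
            raise ValidationError(f"cannot normalize chromosome names on {type(obj)}")
    return out[0] if len(out) == 1 else tuple(out)


def _norm(chrom: str, strip: bool) -> str:
    if strip:
        return chrom[3:] if chrom.lower().startswith("chr") else chrom
    return chrom if chrom.lower().startswith("chr") else "chr" + chrom


# ---------------------------------------------------------------------------
# report serialization

_FLOAT_FMT = "%.12g"  # >= 10 significant digits


def _to_jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(result, path, format: str = "tsv", header: str | None = None) -> None:
    """Serialize a result object to TSV or JSON.

    Accepts :class:`~gsaq.enrichment.GsaqResult`, a hit profile, a pandas
    DataFrame, or any mapping.  Column order is deterministic; floats keep at
    least 10 significant digits; JSON round-trips through
    :func:`json.load` with equal values.
    """
    from .enrichment import GsaqResult  # local import to avoid a cycle
    from .overlap import HitProfile

    if format not in ("tsv", "json"):
        raise ValidationError(f"unknown report format {format!r}")

    if isinstance(result, GsaqResult):
        payload = result.to_dict()
    elif isinstance(result, HitProfile):
        payload = result.to_dict()
    elif isinstance(result, pd.DataFrame):
        payload = result
    elif isinstance(result, Mapping):
        payload = dict(result)
    else:
        raise ValidationError(f"cannot serialize object of type {type(result)}")

    if format == "json":
        with open(path, "w") as fh:
            doc = payload.to_dict(orient="list") if isinstance(payload, pd.DataFrame) else payload
            if header is not None and isinstance(doc, dict):
                doc = {"header": header, **doc}
            json.dump(_to_jsonable(doc), fh, indent=2, sort_keys=False)
            fh.write("\n")
        return

    with open(path, "w") as fh:
        if header is not None:
            fh.write(f"# {header}\n")
        if isinstance(payload, pd.DataFrame):
            payload.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
        elif isinstance(result, GsaqResult):
            fh.write("sample_index\tnqhits\tp_k\n")
            for k, (x, p) in enumerate(zip(result.sample_nqhits, result.sample_pvalues), 1):
                fh.write(f"{k}\t{x}\t{_FLOAT_FMT % p}\n")
            for key in ("method", "statistic", "df", "combined_p", "K", "m",
                        "seed", "N", "N_Q", "n", "tail"):
                fh.write(f"#{key}\t{_fmt_scalar(getattr(result, key))}\n")
        else:
            for key, value in payload.items():
                fh.write(f"{key}\t{_fmt_scalar(value)}\n")


def _fmt_scalar(v) -> str:
    if isinstance(v, (float, np.floating)):
        return _FLOAT_FMT % v
    if isinstance(v, (list, tuple, np.ndarray)):
        return ",".join(_fmt_scalar(x) for x in v)
    return str(v)
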