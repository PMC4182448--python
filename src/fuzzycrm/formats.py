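"""Readers and writers for site annotations, transactions and results.

Supported site-annotation dialects:

* **BED** — tab-separated, >= 4 columns; the name column holds the TF
  label; coordinates already 0-based half-open.
* **GFF3** — 9 columns, 1-based closed coordinates (start is decremented
  on read); the TF label comes from a configurable attribute key
  (default ``Name``).
* **TSV** — header line ``tf_label chrom start end strand [score]``,
  0-based half-open.

The transaction file is the tool's own plain-text dialect: a ``#`` header
line recording the membership parameters, then one transaction per line::

    <id>\t<chrom>:<span_start>-<span_end>\t<TF>:<degree>;<TF>:<degree>;...

with degrees printed to 4 decimal places and TFs sorted lexicographically.
It round-trips through :func:`read_transactions` up to that quantization.
"""
from __future__ import annotations

import urllib.parse
from pathlib import Path

from .mining import FuzzyItemset
from .postprocess import CRMInstance
from .records import TFBSRecord
from .transactions import FuzzyTransaction, FuzzyTransactionDB, MembershipParams

TSV_COLUMNS = ("tf_label", "chrom", "start", "end", "strand", "score")


class FormatError(ValueError):
    """Malformed input line; message names file, line number and field."""


def _err(path, lineno: int, field: str, detail: str) -> FormatError:
    return FormatError(f"{path}:{lineno}: bad {field}: {detail}")


def _parse_int(value: str, path, lineno: int, field: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise _err(path, lineno, field, f"not an integer: {value!r}") from None


def _make_record(tf, chrom, start, end, strand, score, path, lineno) -> TFBSRecord:
    if start >= end:
        raise _err(path, lineno, "interval", f"start {start} >= end {end} after conversion")
    try:
        return TFBSRecord(tf, chrom, start, end, strand, score)
    except ValueError as e:
        raise _err(path, lineno, "record", str(e)) from None


def _read_bed(path) -> list[TFBSRecord]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise _err(path, lineno, "columns", f"expected >= 4 tab-separated, got {len(cols)}")
            start = _parse_int(cols[1], path, lineno, "start")
            end = _parse_int(cols[2], path, lineno, "end")
            strand = cols[5] if len(cols) > 5 and cols[5] else "."
            score = None
            if len(cols) > 4 and cols[4] not in ("", "."):
                try:
                    score = float(cols[4])
                except ValueError:
                    raise _err(path, lineno, "score", f"not a number: {cols[4]!r}") from None
            records.append(_make_record(cols[3], cols[0], start, end, strand, score, path, lineno))
    return records


def _read_gff3(path, attr_key: str) -> list[TFBSRecord]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise _err(path, lineno, "columns", f"expected 9 tab-separated, got {len(cols)}")
            start = _parse_int(cols[3], path, lineno, "start") - 1  # 1-based closed -> 0-based half-open
            end = _parse_int(cols[4], path, lineno, "end")
            strand = cols[6] if cols[6] in ("+", "-") else "."
            score = None
            if cols[5] not in (".", ""):
                try:
                    score = float(cols[5])
                except ValueError:
                    raise _err(path, lineno, "score", f"not a number: {cols[5]!r}") from None
            attrs = {}
            for pair in cols[8].split(";"):
                if "=" in pair:
                    k, v = pair.split("=", 1)
                    attrs[k.strip()] = urllib.parse.unquote(v.strip())
            if attr_key not in attrs:
                raise _err(path, lineno, "attributes", f"missing label attribute {attr_key!r}")
            records.append(_make_record(attrs[attr_key], cols[0], start, end, strand, score, path, lineno))
    return records


def _read_tsv(path) -> list[TFBSRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = list(TSV_COLUMNS[: len(header)])
        if header not in (list(TSV_COLUMNS[:5]), list(TSV_COLUMNS)):
            raise _err(path, 1, "header", f"expected {expected}, got {header}")
        has_score = len(header) == 6
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != len(header):
                raise _err(path, lineno, "columns", f"expected {len(header)}, got {len(cols)}")
            start = _parse_int(cols[2], path, lineno, "start")
            end = _parse_int(cols[3], path, lineno, "end")
            score = None
            if has_score and cols[5] not in ("", "."):
                try:
                    score = float(cols[5])
                except ValueError:
                    raise _err(path, lineno, "score", f"not a number: {cols[5]!r}") from None
            records.append(_make_record(cols[0], cols[1], start, end, cols[4], score, path, lineno))
    return records


def read_tfbs(path, format: str, gff_attr_key: str = "Name") -> list[TFBSRecord]:
    """Read binding-site annotations, converting to 0-based half-open.

    Records preserve file order and are not deduplicated.
    """
    if format == "bed":
        return _read_bed(path)
    if format == "gff3":
        return _read_gff3(path, gff_attr_key)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}; expected bed, gff3 or tsv")


def write_transactions(db: FuzzyTransactionDB, path) -> None:
    """Serialize a transactional database to the transaction dialect."""
    p = db.params
    with open(path, "w") as fh:
        fh.write(
            "# fuzzycrm-transactions v1"
            f"\tmode={db.mode}"
            f"\tcluster_threshold={p.cluster_threshold}"
            f"\tcore_halfwidth={p.core_halfwidth}"
            f"\tramp_width={p.ramp_width}"
            f"\tsite_anchor={p.site_anchor}\n"
        )
        for t in db.transactions:
            items = ";".join(f"{tf}:{t.items[tf]:.4f}" for tf in sorted(t.items))
            fh.write(f"{t.id}\t{t.chrom}:{t.span_start}-{t.span_end}\t{items}\n")


def read_transactions(path) -> FuzzyTransactionDB:
    """Parse a transaction file back into a database (site pools are empty)."""
    params = MembershipParams()
    mode = "fuzzy"
    transactions: list[FuzzyTransaction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                kv = {}
                for tok in line.split("\t")[1:]:
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        kv[k] = v
                if kv:
                    mode = kv.get("mode", mode)
                    params = MembershipParams(
                        cluster_threshold=int(kv.get("cluster_threshold", 300)),
                        core_halfwidth=int(kv.get("core_halfwidth", 150)),
                        ramp_width=int(kv.get("ramp_width", 100)),
                        site_anchor=kv.get("site_anchor", "midpoint"),
                    )
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise _err(path, lineno, "columns", f"expected 3 tab-separated, got {len(cols)}")
            tid, locus, items_str = cols
            try:
                chrom, span = locus.rsplit(":", 1)
                s_start, s_end = span.split("-", 1)
                span_start, span_end = int(s_start), int(s_end)
            except ValueError:
                raise _err(path, lineno, "locus", f"expected chrom:start-end, got {locus!r}") from None
            items: dict[str, float] = {}
            for part in items_str.split(";"):
                if ":" not in part:
                    raise _err(path, lineno, "item", f"expected TF:degree, got {part!r}")
                tf, deg_str = part.rsplit(":", 1)
                try:
                    deg = float(deg_str)
                except ValueError:
                    raise _err(path, lineno, "degree", f"not a number: {deg_str!r}") from None
                if not 0.0 <= deg <= 1.0:
                    raise _err(path, lineno, "degree", f"{deg} outside [0, 1] for {tf!r}")
                if tf in items:
                    raise _err(path, lineno, "item", f"duplicate TF {tf!r} in transaction {tid!r}")
                items[tf] = deg
            transactions.append(
                FuzzyTransaction(id=tid, chrom=chrom, span_start=span_start,
                                 span_end=span_end, items=items)
            )
    return FuzzyTransactionDB(transactions, params=params, mode=mode)


ITEMSET_COLUMNS = ("id", "tf_list", "size", "fuzzy_support", "p_value",
                   "postfit_support", "postfit_dropped")


def write_results(
    itemsets: list[FuzzyItemset],
    instances: list[CRMInstance],
    itemset_path,
    instance_path,
) -> None:
    """Write the ranked itemset table (TSV) and CRM instances (BED).

    Instance BED scores are ``round(1000 * fit_degree)`` so browsers shade
    by fit quality.
    """
    with open(itemset_path, "w") as fh:
        fh.write("\t".join(ITEMSET_COLUMNS) + "\n")
        for i, s in enumerate(itemsets, start=1):
            postfit = "NA" if s.postfit_support is None else f"{s.postfit_support:.6f}"
            pval = "NA" if s.p_value is None else f"{s.p_value:.3e}"
            fh.write(
                f"I{i}\t{','.join(s.items)}\t{s.size}\t{s.fuzzy_support:.6f}"
                f"\t{pval}\t{postfit}\t{int(s.postfit_dropped)}\n"
            )
    with open(instance_path, "w") as fh:
        for inst in instances:
            fh.write(
                f"{inst.chrom}\t{inst.start}\t{inst.end}\t{','.join(inst.itemset)}"
                f"\t{round(1000 * inst.fit_degree)}\t.\n"
            )


def write_truth(truth, path) -> None:
    """Write planted-module ground truth loci as a TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttf_list\n")
        for locus in truth:
            fh.write(f"{locus.chrom}\t{locus.start}\t{locus.end}\t{','.join(locus.tfs)}\n")


def write_bed(sites: list[TFBSRecord], path) -> None:
    """Write site records as 6-column BED."""
    with open(path, "w") as fh:
        for s in sites:
            score = 0 if s.score is None else s.score
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.tf_label}\t{score}\t{s.strand}\n")
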