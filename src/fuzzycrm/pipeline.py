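"""End-to-end orchestration: read -> cluster -> mine -> score -> fit -> write.

The pipeline is deterministic: the same input and configuration always
produce byte-identical outputs. Every run writes a manifest recording the
full configuration, the input checksum and the package version, so a run
can be reproduced from its manifest alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .formats import read_tfbs, read_transactions, write_results, write_transactions
from .mining import FuzzyItemset, mine_database
from .postprocess import CRMInstance, refit_all
from .significance import NullModel, filter_report
from .transactions import (
    FuzzyTransactionDB,
    MembershipParams,
    build_crisp_database,
    build_database,
)

log = logging.getLogger("fuzzycrm")


@dataclass
class RunConfig:
    """All knobs of one screening run; defaults are the documented choices."""

    input_path: str | None = None
    input_format: str = "bed"
    transactions_path: str | None = None  # pre-built transaction file instead
    mode: str = "fuzzy"
    cluster_threshold: int = 300
    core_halfwidth: int = 150
    ramp_width: int = 100
    crisp_halfwidth: int = 250
    site_anchor: str = "midpoint"
    min_support: float = 0.01
    max_pvalue: float = 0.01
    min_size: int = 2
    count_rounding: str = "ceil"
    bh_correction: bool = False
    gff_attr_key: str = "Name"
    seed: int = 0
    outdir: str = "fuzzycrm_out"

    def __post_init__(self) -> None:
        if self.mode not in ("fuzzy", "crisp"):
            raise ValueError("mode must be 'fuzzy' or 'crisp'")
        if not 0.0 <= self.min_support <= 1.0:
            raise ValueError("min_support must be in [0, 1]")
        if not 0.0 < self.max_pvalue <= 1.0:
            raise ValueError("max_pvalue must be in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")

    @property
    def membership_params(self) -> MembershipParams:
        return MembershipParams(
            cluster_threshold=self.cluster_threshold,
            core_halfwidth=self.core_halfwidth,
            ramp_width=self.ramp_width,
            site_anchor=self.site_anchor,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunResult:
    """In-memory results plus per-stage counts."""

    itemsets: list[FuzzyItemset]
    instances: list[CRMInstance]
    db: FuzzyTransactionDB
    counts: dict[str, int] = field(default_factory=dict)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_run_database(config: RunConfig) -> FuzzyTransactionDB:
    """Construct the transactional database per the configured mode."""
    if config.transactions_path is not None:
        db = read_transactions(config.transactions_path)
        log.info("loaded %d transactions from %s", db.N, config.transactions_path)
        return db
    if config.input_path is None:
        raise ValueError("either input_path or transactions_path is required")
    sites = read_tfbs(config.input_path, config.input_format, config.gff_attr_key)
    log.info("read %d sites from %s", len(sites), config.input_path)
    params = config.membership_params
    if config.mode == "crisp":
        db = build_crisp_database(sites, params, config.crisp_halfwidth)
    else:
        db = build_database(sites, params)
    log.info(
        "built %d %s transactions (%d empty clusters dropped)",
        db.N, db.mode, db.n_empty_dropped,
    )
    return db


def analyze_database(config: RunConfig, db: FuzzyTransactionDB) -> RunResult:
    """Mine, score and refit a database; no I/O."""
    header, mined = mine_database(db, config.min_support, config.min_size)
    null = NullModel.from_database(db)
    reported = filter_report(
        mined, null, config.max_pvalue, config.min_support,
        config.count_rounding, config.bh_correction,
    )
    instances, reported = refit_all(db, reported, config.min_support)
    counts = {
        "transactions": db.N,
        "empty_clusters_dropped": db.n_empty_dropped,
        "frequent_items": len(header),
        "itemsets_mined": len(mined),
        "itemsets_reported": len(reported),
        "instances": len(instances),
    }
    for k, v in counts.items():
        log.info("%s: %d", k, v)
    return RunResult(itemsets=reported, instances=instances, db=db, counts=counts)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifacts to ``outdir``.

    Artifacts: ``transactions.tsv``, ``itemsets.tsv``, ``instances.bed``
    and ``manifest.json``. An empty result set is a success with
    header-only outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = build_run_database(config)
    result = analyze_database(config, db)

    write_transactions(db, outdir / "transactions.tsv")
    write_results(result.itemsets, result.instances,
                  outdir / "itemsets.tsv", outdir / "instances.bed")
    manifest = {
        "tool": "fuzzycrm",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": _sha256(config.input_path) if config.input_path else None,
        "transactions_sha256": (
            _sha256(config.transactions_path) if config.transactions_path else None
        ),
        "counts": result.counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


@dataclass
class ModeComparison:
    """Union of fuzzy and crisp itemsets with both scores, plus summary means."""

    rows: list[dict]
    summary: dict[str, float]


def compare_modes(config: RunConfig) -> ModeComparison:
    """Run fuzzy and crisp modes on the same input and tabulate both.

    Each row carries the itemset, both supports and p-values, and flags
    for membership in each result set; the summary holds the mean support
    and mean p-value per mode over its own result set.
    """
    fuzzy_cfg = dataclasses.replace(config, mode="fuzzy")
    crisp_cfg = dataclasses.replace(config, mode="crisp")
    fuzzy = analyze_database(fuzzy_cfg, build_run_database(fuzzy_cfg))
    crisp = analyze_database(crisp_cfg, build_run_database(crisp_cfg))

    f_by = {s.items: s for s in fuzzy.itemsets}
    c_by = {s.items: s for s in crisp.itemsets}
    rows = []
    for items in sorted(set(f_by) | set(c_by)):
        f, c = f_by.get(items), c_by.get(items)
        rows.append({
            "tf_list": ",".join(items),
            "fuzzy_support": f.fuzzy_support if f else None,
            "fuzzy_p_value": f.p_value if f else None,
            "crisp_support": c.fuzzy_support if c else None,
            "crisp_p_value": c.p_value if c else None,
            "in_fuzzy": f is not None,
            "in_crisp": c is not None,
        })

    def mean(xs):
        xs = list(xs)
        return sum(xs) / len(xs) if xs else float("nan")

    summary = {
        "n_fuzzy": len(fuzzy.itemsets),
        "n_crisp": len(crisp.itemsets),
        "mean_fuzzy_support": mean(s.fuzzy_support for s in fuzzy.itemsets),
        "mean_crisp_support": mean(s.fuzzy_support for s in crisp.itemsets),
        "mean_fuzzy_p_value": mean(s.p_value for s in fuzzy.itemsets),
        "mean_crisp_p_value": mean(s.p_value for s in crisp.itemsets),
    }
    return ModeComparison(rows=rows, summary=summary)


def write_comparison(comparison: ModeComparison, path) -> None:
    """Serialize a mode comparison as TSV with summary comment lines."""
    cols = ("tf_list", "fuzzy_support", "fuzzy_p_value",
            "crisp_support", "crisp_p_value", "in_fuzzy", "in_crisp")
    with open(path, "w") as fh:
        for k, v in comparison.summary.items():
            fh.write(f"# {k}={v:.6g}\n" if isinstance(v, float) else f"# {k}={v}\n")
        fh.write("\t".join(cols) + "\n")
        for row in comparison.rows:
            vals = []
            for c in cols:
                v = row[c]
                if v is None:
                    vals.append("NA")
                elif isinstance(v, bool):
                    vals.append(str(int(v)))
                elif isinstance(v, float):
                    vals.append(f"{v:.6g}")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
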