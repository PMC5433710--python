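"""End-to-end orchestration: conserve -> mapvariants -> reports.

``run_conserve`` produces the per-column site table (Ind1/Ind2/Ind3,
SLAC, radical-change summaries), per-gene summaries with GTR+G+I mean
distances and indel events, index distribution summaries and
exponential fits.  ``run_mapvariants`` maps a disease-variant table
onto the alignment, emits per-variant recurrence reports, the gene x
status position summaries, and the Kolmogorov-Smirnov / t-test
comparisons.  ``run_simulate`` wraps the synthetic generator.

Every emitted TSV starts with comment lines naming the package version
and the configuration hash, and identical configuration + inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conservation import (
    GeneSummary,
    aa_substitutions,
    enumerate_indel_events,
    included_columns,
    site_conservation_table,
    size_distance_correlation,
)
from .distances import gene_mean_distance
from .io import (
    CodonAlignment,
    Phylogeny,
    read_codon_alignment,
    read_rename_map,
    read_variants,
)
from .physchem import RadicalChangeModel, codon_usage_of, site_radical_summary
from .rates import site_rates
from .reference import GeneMap
from .simulate import (
    SimulationConfig,
    plant_variants,
    simulate_alignment,
    write_bundle,
)
from .stats import exponential_gof, ks_two_sample, two_sample_t
from .variants import CladeRegistry, recurrence_report, summarize

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    alignment: str
    tree: str
    outdir: str = "results"
    gene_map: str | None = None  # None -> packaged rCRS map
    gene_offsets: str | None = None  # TSV gene/start/end (codon columns)
    variants: str | None = None
    scores: str | None = None
    rename_map: str | None = None
    clades: str | None = None  # TSV taxon/species/clades
    reference_taxon: str = "REF"
    drop_reference_gaps: bool = True
    drop_terminal_stops: bool = True
    slac_alpha: float = 0.1
    ind3_categories: int = 16
    radical_mode: str = "z"  # 'z' | 'category'
    gof_bins: dict = field(
        default_factory=lambda: {"ind1": 16, "ind2": 9, "ind3": 10}
    )
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        )


def _header(cfg: RunConfig) -> str:
    return (
        f"# mtconserv {__version__}\n"
        f"# config {cfg.digest()}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_inputs(
    cfg: RunConfig,
) -> tuple[CodonAlignment, Phylogeny]:
    """Read and bind the alignment and tree named by the config."""
    apath = Path(cfg.alignment)
    if apath.is_dir():
        parts = []
        for f in sorted(apath.glob("*.fasta")) + sorted(apath.glob("*.fas")):
            parts.append(read_codon_alignment(f, gene=f.stem))
        if not parts:
            raise FileNotFoundError(f"no FASTA files in {apath}")
        taxa = parts[0].taxa
        mats, prov = [], []
        for p in parts:
            if p.taxa != taxa:
                raise ValueError(f"taxon sets differ across {apath}")
            mats.append(p.codons)
            prov.extend(p.provenance)
        aln = CodonAlignment(
            gene="concat", taxa=taxa, codons=np.hstack(mats), provenance=prov
        )
    else:
        aln = read_codon_alignment(apath)
        if cfg.gene_offsets:
            off = pd.read_csv(cfg.gene_offsets, sep="\t")
            prov = list(aln.provenance)
            for r in off.itertuples():
                for k, j in enumerate(range(int(r.start) - 1, int(r.end))):
                    prov[j] = (r.gene, k + 1)
            aln.provenance = prov
    tree = Phylogeny.from_newick(cfg.tree)
    rename = read_rename_map(cfg.rename_map) if cfg.rename_map else None
    tree.bind(aln, rename)
    return aln, tree


def run_conserve(cfg: RunConfig) -> dict[str, object]:
    """Site conservation table, gene summaries, indels, distributions."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, tree = load_inputs(cfg)
    ref = cfg.reference_taxon if cfg.reference_taxon in aln.taxa else None
    cols = included_columns(
        aln, ref, cfg.drop_reference_gaps, cfg.drop_terminal_stops
    )
    site = site_conservation_table(
        aln, tree, reference_taxon=ref, columns=cols, alpha=cfg.slac_alpha
    )
    aa = aln.aa_matrix()
    rates = site_rates(tree, aa, columns=cols,
                       n_categories=cfg.ind3_categories)
    site["ind3"] = rates.standardized

    # genome-wide substitution inventory -> radical-change model
    inventory: list[tuple[str, str]] = []
    per_column_subs: dict[int, list[tuple[str, str]]] = {}
    for j in cols:
        subs = aa_substitutions(tree, aa[:, j]) or []
        per_column_subs[j] = [(a, b) for _, a, b in subs]
        inventory.extend(per_column_subs[j])
    usage = codon_usage_of(aln.codons[:, cols])
    model = RadicalChangeModel.from_inventory(
        inventory,
        codon_usage=usage or None,
        category_only=(cfg.radical_mode == "category") or not inventory,
    )
    rad = {
        j: site_radical_summary(per_column_subs[j], model) for j in cols
    }
    site["n_radical_substitutions"] = [rad[j][0] for j in site["column"]]
    site["max_radical_properties"] = [rad[j][1] for j in site["column"]]

    # per-gene summaries
    genes = sorted({g for g, _ in aln.provenance})
    indels = enumerate_indel_events(aln, tree)
    summaries = []
    for g in genes:
        gcols = [j for j in range(aln.n_columns)
                 if aln.provenance[j][0] == g]
        sub = aln.subalignment(gcols)
        mean_d = gene_mean_distance(sub)
        gsite = site[site["gene"] == g]
        frac = (
            float(gsite["negatively_selected"].mean()) if len(gsite) else 0.0
        )
        summaries.append(
            GeneSummary(
                gene=g,
                length_bp=3 * len(gcols),
                mean_distance=mean_d,
                fraction_negative=frac,
                n_indel_events=sum(1 for e in indels if e.gene == g),
            )
        )
    gene_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    indel_df = pd.DataFrame(
        [dataclasses.asdict(e) for e in indels]
    )

    dist = {}
    for name in ("ind1", "ind2", "ind3"):
        v = site[name].dropna().astype(float)
        if not len(v):
            continue
        vals, counts = np.unique(v, return_counts=True)
        entry = {
            "mode": float(vals[counts.argmax()]),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
        if name == "ind3":
            entry["median"] = float(v.median())
            v = v - v.min()  # shift to positive support
        if v.mean() > 0:
            gof = exponential_gof(v, n_bins=cfg.gof_bins.get(name, 16))
            entry["exponential_chi2"] = gof.statistic
            entry["exponential_df"] = gof.df
            entry["exponential_p"] = gof.p_value
        dist[name] = entry
    dist["n_columns"] = int(len(site))
    dist["n_invariant"] = int((site["ind1"] == 1).sum())
    dist["fraction_negative"] = float(site["negatively_selected"].mean())
    dist["fraction_negative_strict"] = float(
        site["negatively_selected_strict"].mean()
    )
    dist["correlations"] = size_distance_correlation(summaries)
    dist["ind3_alpha"] = rates.alpha

    _write_tsv(site, outdir / "site_conservation.tsv", cfg)
    _write_tsv(gene_df, outdir / "gene_summary.tsv", cfg)
    _write_tsv(indel_df, outdir / "indel_events.tsv", cfg)
    (outdir / "distributions.json").write_text(
        json.dumps(dist, indent=1, sort_keys=True)
    )
    return {
        "site": site,
        "genes": gene_df,
        "indels": indel_df,
        "distributions": dist,
        "alignment": aln,
        "tree": tree,
    }


def run_mapvariants(cfg: RunConfig) -> dict[str, object]:
    """Per-variant recurrence reports and comparative statistics."""
    if cfg.variants is None:
        raise ValueError("config names no variant table")
    outdir = Path(cfg.outdir)
    site_path = outdir / "site_conservation.tsv"
    if site_path.exists():
        site = _read_tsv(site_path)
        aln, tree = load_inputs(cfg)
    else:
        res = run_conserve(cfg)
        site, aln, tree = res["site"], res["alignment"], res["tree"]
    ref = cfg.reference_taxon
    gmap = GeneMap.from_tsv(cfg.gene_map) if cfg.gene_map else GeneMap.rcrs()
    if cfg.clades:
        clades = CladeRegistry.from_tsv(cfg.clades, human=ref)
    else:
        clades = CladeRegistry.nested_from_tree(tree, human=ref)
    variants = read_variants(cfg.variants)
    if cfg.scores:
        scores = pd.read_csv(cfg.scores, sep="\t")
        by_notation = dict(zip(scores["notation"], scores["score"]))
        for v in variants:
            v.score = by_notation.get(v.notation, v.score)
    aa = aln.aa_matrix()
    reports = [
        recurrence_report(
            v, aln, tree, clades, ref, gmap=gmap, site_table=site,
            aa_matrix=aa,
        )
        for v in variants
    ]
    mappable = [r for r in reports
                if r.primary_target and r.primary_target.column is not None]
    if not mappable:
        log.warning("no variant mapped inside protein-coding genes")

    report_rows = []
    for r in reports:
        t = r.primary_target
        report_rows.append(
            {
                "notation": r.variant.notation,
                "status": r.variant.status,
                "gene": t.gene if t else None,
                "codon": t.codon if t else None,
                "column": t.column if t else None,
                "kind": t.kind if t else "unmapped",
                "disease_residue": r.disease_residue,
                "in_primates": r.present_in_nonhuman_primates,
                "in_catarrhines": r.present_in_catarrhines,
                "in_hominids": r.present_in_hominids,
                "in_extinct_homo": r.present_in_extinct_homo,
                "n_independent_origins": r.n_independent_origins,
                "n_species_with_residue": r.n_species_with_residue,
                "is_reversion": r.is_reversion,
                "ind1": r.ind1,
                "ind2": r.ind2,
                "ind3": r.ind3,
                "negatively_selected": r.negatively_selected,
                "reason": r.reason,
            }
        )
    reports_df = pd.DataFrame(report_rows)
    radical_by_column = dict(
        zip(site["column"], site["n_radical_substitutions"])
    ) if "n_radical_substitutions" in site.columns else None
    tables = summarize(reports, site, radical_by_column)

    # index distributions: all columns vs confirmed vs reported positions
    stats_out: dict[str, object] = {}
    cols_by_status = {
        status: sorted(
            {
                r.primary_target.column
                for r in mappable
                if r.variant.status == status
            }
        )
        for status in ("confirmed", "reported")
    }
    site_by_col = site.set_index("column")
    for index_name in ("ind1", "ind2", "ind3"):
        if index_name not in site.columns:
            continue
        groups = {"all": site[index_name].dropna().astype(float).to_numpy()}
        for status, cols in cols_by_status.items():
            cols = [c for c in cols if c in site_by_col.index]
            vals = site_by_col.loc[cols, index_name].dropna()
            groups[status] = vals.astype(float).to_numpy()
        comp = {}
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if len(groups[a]) and len(groups[b]):
                    res = ks_two_sample(groups[a], groups[b])
                    comp[f"{a}_vs_{b}"] = {
                        "D": res.statistic,
                        "p": res.p_value,
                        "n": res.n,
                    }
        stats_out[index_name] = comp
    scored = {
        s: [r.variant.score for r in mappable
            if r.variant.status == s and r.variant.score is not None]
        for s in ("confirmed", "reported")
    }
    if all(len(v) >= 2 for v in scored.values()):
        t_res = two_sample_t(scored["confirmed"], scored["reported"])
        stats_out["pathogenicity_t"] = {
            "t": t_res.statistic,
            "df": t_res.df,
            "p": t_res.p_value,
            "n": t_res.n,
        }
    stats_out["n_positions"] = {
        s: len(c) for s, c in cols_by_status.items()
    }
    stats_out["n_variants"] = len(variants)

    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(reports_df, outdir / "variant_reports.tsv", cfg)
    for name, df in tables.items():
        if isinstance(df, pd.DataFrame) and len(df):
            _write_tsv(df, outdir / f"{name}.tsv", cfg)
    (outdir / "variant_stats.json").write_text(
        json.dumps(stats_out, indent=1, sort_keys=True)
    )
    return {
        "reports": reports,
        "reports_df": reports_df,
        "tables": tables,
        "stats": stats_out,
    }


def run_simulate(
    sim_cfg: SimulationConfig,
    outdir: str | Path,
    n_confirmed: int = 28,
    n_reported: int = 192,
) -> dict[str, object]:
    """Generate a synthetic bundle consumable by ``run_conserve``."""
    aln, tree, truth = simulate_alignment(sim_cfg)
    variants = plant_variants(
        aln, tree, truth, n_conserved=n_confirmed, n_variable=n_reported,
        seed=sim_cfg.seed + 1,
    )
    manifest = write_bundle(outdir, sim_cfg, aln, tree, truth, variants)
    return {
        "alignment": aln,
        "tree": tree,
        "truth": truth,
        "variants": variants,
        "manifest": manifest,
    }
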