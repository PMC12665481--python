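"""End-to-end orchestration: geochemistry -> ecology -> combined report.

Each run stage reads/writes plain TSV with '#'-prefixed header lines that
record the package version, a hash of the configuration, and every seed, so
reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from . import datasets
from .chem_io import read_chemistry, records_to_frame
from .ecology import (AsvTable, DistanceMatrix, observed_richness, pcoa,
                      permanova, rarefy, spearman_matrix, unifrac_unweighted,
                      ward_hac)
from .speciation import (adjust_electrical_balance, in_situ_speciation,
                         saturation_index)
from .thermo_kinetics import (gibbs_from_si, reactivity_table,
                              redox_potential, results_to_frame,
                              summarize_reactivity)

__all__ = ["RunConfig", "run_geochem", "run_ecology", "run_report",
           "derive_mode_b_inputs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    chemistry: Optional[str] = None        # chemistry CSV (None = bundled table)
    reactivity: Optional[str] = None       # mode-A inputs CSV (None = bundled)
    asv_table: Optional[str] = None        # TSV, rows = ASVs
    tree: Optional[str] = None             # newick
    metadata: Optional[str] = None         # TSV keyed by sample id
    mode: str = "A"
    rarefaction_depth: int = 6000
    rarefaction_seed: int = 1
    n_perm: int = 999
    perm_seed: int = 1
    out_dir: str = "results"
    force: bool = False

    def config_hash(self) -> str:
        # hash the scientific parameters only, so identical analyses run
        # into different directories produce identical outputs
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "force")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, seeds: dict) -> None:
    if path.exists() and not config.force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    header = (f"# basaltbiome {__version__}  config={config.config_hash()}  "
              + "  ".join(f"{k}={v}" for k, v in sorted(seeds.items())))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def _load_records(config: RunConfig):
    if config.chemistry is None:
        return datasets.load_well_chemistry()
    return read_chemistry(config.chemistry)


def derive_mode_b_inputs(records, constants=None) -> pd.DataFrame:
    """Full-speciation ("mode B") per-well reactivity inputs.

    For each well: adjust the electrical balance at 20 degC, speciate at
    the wellhead temperature, convert saturation indices to Gibbs free
    energies, and evaluate the sulfate-sulfide redox potential from
    speciated activities.  Quantities whose inputs are missing are null.
    """
    constants = constants or datasets.default_thermo_constants()
    rows = []
    for rec in records:
        adj = adjust_electrical_balance(rec, constants)
        water = in_situ_speciation(rec, constants, multipliers=adj.multipliers)
        row = {"well_id": rec.well_id, "pH_T": water.pH_T,
               "delta_pH_20": adj.delta_pH, "balanced": adj.balanced}
        for phase, col in (("forsterite", "dG_Fo_kJ_mol"),
                           ("basaltic_glass", "dG_BG_kJ_mol")):
            si = saturation_index(water, phase, constants)
            dg = gibbs_from_si(si, water.T)
            row[col] = np.nan if dg is None else dg / 1000.0
        a_so4 = water.activity("SO42-")
        a_h2s = water.activity("H2S(aq)")
        if a_so4 and a_h2s:
            logk = constants.logK("sulfate_sulfide", rec.T_wellhead)
            row["EH_V"] = redox_potential(a_so4, a_h2s, water.activity("H+"),
                                          water.T, logk)
        else:
            row["EH_V"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("well_id")


def run_geochem(config: RunConfig):
    """Chemistry -> reactivity table + summary; writes two TSVs."""
    records = _load_records(config)
    if len(records) == 0:
        raise ValueError("no wells in chemistry input")
    chem = records_to_frame(records)
    if config.mode == "A":
        if config.reactivity is None:
            inputs = datasets.load_reactivity_reference()
        else:
            inputs = pd.read_csv(config.reactivity, na_values=["n.d."]).set_index("well_id")
    elif config.mode == "B":
        inputs = derive_mode_b_inputs(records)
    else:
        raise ValueError("mode must be 'A' or 'B'")
    kinetics = datasets.default_phase_kinetics()
    results = reactivity_table(chem["T_wellhead"], inputs, kinetics)
    table = results_to_frame(results)
    summary = summarize_reactivity(results)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(table, out / "reactivity.tsv", config, {"mode": config.mode})
    _write_tsv(summary, out / "reactivity_summary.tsv", config, {"mode": config.mode})
    return table, summary


def _load_ecology_inputs(config: RunConfig):
    counts = pd.read_csv(config.asv_table, sep="\t", index_col=0)
    table = AsvTable.from_frame(counts, orientation="asv_rows")
    tree = dendropy.Tree.get(path=config.tree, schema="newick",
                             preserve_underscores=True)
    meta = pd.read_csv(config.metadata, sep="\t", index_col=0, comment="#")
    return table, tree, meta


def run_ecology(config: RunConfig):
    """ASV table + tree + metadata -> distances, ordination, PERMANOVA, correlations."""
    table, tree, meta = _load_ecology_inputs(config)
    table = rarefy(table, config.rarefaction_depth, config.rarefaction_seed)
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"sample id(s) missing from metadata: {missing}")
    meta = meta.loc[table.sample_ids]

    D = unifrac_unweighted(table, tree)
    ord_ = pcoa(D)
    Z = ward_hac(D)
    rich = observed_richness(table)

    perm_rows = []
    for var in meta.columns:
        x = pd.to_numeric(meta[var], errors="coerce")
        ok = ~x.isna()
        if ok.sum() < 3 or x[ok].nunique() < 2:
            continue
        sub = DistanceMatrix(D.data[np.ix_(ok.to_numpy(), ok.to_numpy())],
                             [s for s, m in zip(D.ids, ok) if m])
        res = permanova(sub, x[ok].to_frame(), n_perm=config.n_perm,
                        seed=config.perm_seed)
        perm_rows.append({"variable": var, "R2": res["R2"],
                          "pseudo_F": res["pseudo_F"], "p": res["p"],
                          "n": int(ok.sum())})
    perm_table = (pd.DataFrame(perm_rows).set_index("variable")
                  .sort_values("R2", ascending=False))

    corr = spearman_matrix(meta.apply(pd.to_numeric, errors="coerce"))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {"rarefaction_seed": config.rarefaction_seed,
             "perm_seed": config.perm_seed, "depth": config.rarefaction_depth}
    _write_tsv(D.to_frame(), out / "unifrac.tsv", config, seeds)
    _write_tsv(ord_.to_frame(), out / "pcoa.tsv", config, seeds)
    _write_tsv(pd.DataFrame(Z, columns=["left", "right", "height", "size"]),
               out / "ward_linkage.tsv", config, seeds)
    _write_tsv(rich.to_frame(), out / "richness.tsv", config, seeds)
    _write_tsv(perm_table, out / "permanova.tsv", config, seeds)
    _write_tsv(corr["rho"], out / "spearman_rho.tsv", config, seeds)
    return {"distance": D, "pcoa": ord_, "linkage": Z, "richness": rich,
            "permanova": perm_table, "spearman": corr}


#: predictor pairs more correlated than this are flagged in the report
COLLINEARITY_RHO = 0.7


def run_report(config: RunConfig):
    """Join geochemical predictors into the ecology metadata and re-test.

    Derived predictors (dissolution rates, Gibbs free energies, redox
    potential, in-situ pH) become PERMANOVA terms alongside the measured
    ones; wells lacking a given variable are dropped for that variable only.
    Highly correlated predictor pairs (|rho| > 0.7) are flagged, never
    dropped automatically.
    """
    out = Path(config.out_dir)
    react_path = out / "reactivity.tsv"
    uni_path = out / "unifrac.tsv"
    for p, stage in ((react_path, "geochem"), (uni_path, "ecology")):
        if not p.exists():
            raise FileNotFoundError(f"missing upstream output {p}; run the "
                                    f"{stage} stage first")
    react = pd.read_csv(react_path, sep="\t", comment="#", index_col=0)
    D_frame = pd.read_csv(uni_path, sep="\t", comment="#", index_col=0)
    meta = pd.read_csv(config.metadata, sep="\t", index_col=0, comment="#")

    joined = meta.join(react[["pH_T", "dG_Fo_kJ_mol", "dG_BG_kJ_mol",
                              "r_Fo", "r_BG", "EH_V"]], how="left")
    samples = [s for s in D_frame.index if s in joined.index]
    D = DistanceMatrix(D_frame.loc[samples, samples].to_numpy(), samples)
    joined = joined.loc[samples]

    rows = []
    for var in joined.columns:
        x = pd.to_numeric(joined[var], errors="coerce")
        ok = ~x.isna()
        if ok.sum() < 3 or x[ok].nunique() < 2:
            continue
        sub = DistanceMatrix(D.data[np.ix_(ok.to_numpy(), ok.to_numpy())],
                             [s for s, m in zip(D.ids, ok) if m])
        res = permanova(sub, x[ok].to_frame(), n_perm=config.n_perm,
                        seed=config.perm_seed)
        rows.append({"variable": var, "R2": res["R2"], "pseudo_F": res["pseudo_F"],
                     "p": res["p"], "n": int(ok.sum())})
    report = (pd.DataFrame(rows).set_index("variable")
              .sort_values("R2", ascending=False))

    corr = spearman_matrix(joined.apply(pd.to_numeric, errors="coerce"))
    rho = corr["rho"]
    flags = []
    cols = list(rho.columns)
    for i, a in enumerate(cols):
        for bcol in cols[i + 1:]:
            v = rho.loc[a, bcol]
            if pd.notna(v) and abs(v) > COLLINEARITY_RHO:
                flags.append({"var_a": a, "var_b": bcol, "rho": v})
    flags = pd.DataFrame(flags, columns=["var_a", "var_b", "rho"])

    cfg2 = RunConfig(**{**asdict(config), "force": True})
    _write_tsv(report, out / "report_permanova.tsv", cfg2,
               {"perm_seed": config.perm_seed})
    _write_tsv(flags.set_index("var_a") if len(flags) else flags,
               out / "report_collinearity.tsv", cfg2,
               {"perm_seed": config.perm_seed})
    return {"permanova": report, "collinearity": flags, "predictors": joined}
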