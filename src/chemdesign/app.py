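"""Command-line interface tying the design pipeline together.

Subcommands mirror the workflow: ``make-fixtures`` (synthetic corpus and
property tables), ``train-lm`` / ``sample`` / ``perplexity`` (chemical
language model), ``fit-qspr`` / ``predict`` / ``evaluate`` (forward models),
and ``design`` (the tempered SMC backward prediction).  Every stochastic
subcommand takes an explicit seed, and every output directory receives a
machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .chemstring import read_smiles_file, tokenize, write_smiles_file
from .datafix import (
    SyntheticPropertySpec,
    ToyCorpusSpec,
    make_synthetic_property,
    make_toy_corpus,
    read_property_csv,
)
from .forward import FingerprintSpec, PropertyRegion, QSPRModel, evaluate_fingerprints
from .langmodel import LanguageModel, fit_from_smiles
from .smc import SMCConfig, design

logger = logging.getLogger("chemdesign")


def _write_manifest(path: Path, command: str, params: dict) -> None:
    manifest = {"tool": "chemdesign", "version": __version__, "command": command,
                "params": params}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


@click.group()
@click.option("--log-level", default="INFO", show_default=True,
              type=click.Choice(["DEBUG", "INFO", "WARNING", "ERROR"]))
def cli(log_level):
    """Bayesian molecular design with a chemical language model."""
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, log_level),
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command("make-fixtures")
@click.option("--out-dir", type=click.Path(path_type=Path), required=True)
@click.option("--n-molecules", default=2000, show_default=True)
@click.option("--max-heavy-atoms", default=18, show_default=True)
@click.option("--ring-probability", default=0.35, show_default=True)
@click.option("--branch-probability", default=0.25, show_default=True)
@click.option("--noise-sd", default=0.1, show_default=True)
@click.option("--seed", default=0, show_default=True)
def make_fixtures(out_dir, n_molecules, max_heavy_atoms, ring_probability,
                  branch_probability, noise_sd, seed):
    """Write a synthetic SMILES corpus and a two-property table."""
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = ToyCorpusSpec(n_molecules=n_molecules, max_heavy_atoms=max_heavy_atoms,
                         ring_probability=ring_probability,
                         branch_probability=branch_probability, seed=seed)
    corpus = make_toy_corpus(spec)
    write_smiles_file(out_dir / "corpus.smi", corpus)
    rng = np.random.default_rng(seed + 1)
    fp = FingerprintSpec(("circular",), n_bits=256)
    gap = make_synthetic_property(
        corpus, SyntheticPropertySpec(fp, noise_sd=noise_sd, name="gap_ev", units="eV"), rng)
    energy = make_synthetic_property(
        corpus, SyntheticPropertySpec(fp, noise_sd=noise_sd, weight_scale=2.0,
                                      name="energy_kcal_mol", units="kcal/mol"), rng)
    table = gap.table.merge(energy.table, on="smiles")
    table.to_csv(out_dir / "properties.csv", index=False)
    _write_manifest(out_dir / "manifest.json", "make-fixtures",
                    {"seed": seed, "n_molecules": n_molecules,
                     "corpus": "corpus.smi", "properties": "properties.csv"})
    click.echo(f"wrote {len(corpus)} molecules to {out_dir}")


@cli.command("train-lm")
@click.option("--corpus", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--n", "n_max", default=10, show_default=True, help="Markov order")
@click.option("--smoothing", default="backoff", show_default=True,
              type=click.Choice(["backoff", "kneser_ney"]))
@click.option("--out", type=click.Path(path_type=Path), required=True)
def train_lm(corpus, n_max, smoothing, out):
    """Train the stratified n-gram chemical language model."""
    smiles = read_smiles_file(corpus)
    model = fit_from_smiles(smiles, n_max, smoothing=smoothing)
    model.save(out)
    _write_manifest(out.with_suffix(".manifest.json"), "train-lm",
                    {"corpus": str(corpus), "n": n_max, "smoothing": smoothing,
                     "n_strings": len(smiles), "vocab_size": len(model.vocab)})
    click.echo(f"trained n={n_max} {smoothing} model on {len(smiles)} strings -> {out}")


@cli.command("sample")
@click.option("--lm", "lm_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--n-samples", default=100, show_default=True)
@click.option("--max-tokens", default=200, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(path_type=Path), default=None,
              help="output SMILES file (default: stdout)")
def sample(lm_path, n_samples, max_tokens, seed, out):
    """Generate molecules from a trained language model."""
    from .chemstring import grammar_check, to_smiles

    model = LanguageModel.load(lm_path)
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_samples):
        seq = model.generate(None, max_tokens, rng)
        if not seq.complete:
            continue
        try:
            smi = to_smiles(seq)
        except ValueError:
            continue
        if grammar_check(smi):
            results.append(smi)
    if out is None:
        for s in results:
            click.echo(s)
    else:
        write_smiles_file(out, results)
        click.echo(f"{len(results)}/{n_samples} valid molecules -> {out}")


@cli.command("perplexity")
@click.option("--lm", "lm_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--corpus", type=click.Path(exists=True, path_type=Path), required=True)
def perplexity_cmd(lm_path, corpus):
    """Held-out perplexity of a trained model on a SMILES corpus."""
    model = LanguageModel.load(lm_path)
    toks = [tokenize(s) for s in read_smiles_file(corpus)]
    click.echo(f"{model.perplexity(toks):.6g}")


@cli.command("fit-qspr")
@click.option("--data", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--smiles-col", default="smiles", show_default=True)
@click.option("--property-col", required=True)
@click.option("--units", default="", show_default=True)
@click.option("--components", default="path,layered,circular", show_default=True)
@click.option("--bits", default=1024, show_default=True)
@click.option("--out", type=click.Path(path_type=Path), required=True)
def fit_qspr(data, smiles_col, property_col, units, components, bits, out):
    """Fit the Bayesian linear QSPR model for one property."""
    smiles, Y, report = read_property_csv(data, smiles_col, (property_col,))
    spec = FingerprintSpec(tuple(components.split(",")), n_bits=bits)
    model = QSPRModel.fit(smiles, Y[:, 0], spec, name=property_col, units=units)
    model.save(out)
    logger.info("dropped %d bad-smiles and %d bad-value rows",
                report.n_bad_smiles, report.n_bad_values)
    _write_manifest(out.with_suffix(".manifest.json"), "fit-qspr",
                    {"data": str(data), "property": property_col,
                     "components": components, "bits": bits,
                     "n_train": model.n_train, "n_dropped": model.n_dropped})
    click.echo(f"fit {property_col} on {model.n_train} molecules -> {out}")


@cli.command("predict")
@click.option("--model", "model_path", type=click.Path(exists=True, path_type=Path),
              required=True)
@click.option("--input", "input_path", type=click.Path(exists=True, path_type=Path),
              required=True, help="SMILES file, one per line")
@click.option("--out", type=click.Path(path_type=Path), default=None)
def predict_cmd(model_path, input_path, out):
    """Predictive means for a list of molecules."""
    model = QSPRModel.load(model_path)
    smiles = read_smiles_file(input_path)
    preds = model.predict(smiles)
    df = pd.DataFrame({"smiles": smiles, model.name: preds})
    if out is None:
        click.echo(df.to_csv(index=False).rstrip())
    else:
        df.to_csv(out, index=False)
        click.echo(f"wrote {len(df)} predictions -> {out}")


@cli.command("evaluate")
@click.option("--data", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--smiles-col", default="smiles", show_default=True)
@click.option("--property-cols", default="gap_ev,energy_kcal_mol", show_default=True)
@click.option("--combos", default="path;layered;circular;maccs;path+layered+circular;path+layered+circular+maccs",
              show_default=True, help="';'-separated '+'-joined component sets")
@click.option("--n-train", default=10000, show_default=True)
@click.option("--bits", default=1024, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(path_type=Path), default=None)
def evaluate(data, smiles_col, property_cols, combos, n_train, bits, seed, out):
    """Descriptor comparison: test MAE per fingerprint combination."""
    props = tuple(property_cols.split(","))
    smiles, Y, _ = read_property_csv(data, smiles_col, props)
    combo_list = [tuple(c.split("+")) for c in combos.split(";")]
    df = evaluate_fingerprints(smiles, Y, list(props), combo_list,
                               n_train=min(n_train, max(len(smiles) - 1, 1)),
                               n_bits=bits, seed=seed)
    if out is None:
        click.echo(df.to_string(index=False))
    else:
        df.to_csv(out, index=False)
        click.echo(f"wrote MAE table -> {out}")


@cli.command("design")
@click.option("--lm", "lm_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--qspr", required=True, help="comma-separated QSPR model JSON files")
@click.option("--region", required=True, help='property box "lo:hi,lo:hi"')
@click.option("--seed-smiles", default="c1ccccc1O", show_default=True)
@click.option("--r", "-R", "R", default=100, show_default=True, help="population size")
@click.option("--t", "-T", "T", default=500, show_default=True, help="iterations")
@click.option("--kappa", default=0.2, show_default=True)
@click.option("--eta", default=0.5, show_default=True)
@click.option("--l", "-L", "L", default=5, show_default=True)
@click.option("--ess-threshold", default=50.0, show_default=True)
@click.option("--rng-seed", default=0, show_default=True)
@click.option("--top-k", default=10, show_default=True)
@click.option("--tanimoto-threshold", default=0.9, show_default=True)
@click.option("--out", type=click.Path(path_type=Path), required=True)
def design_cmd(lm_path, qspr, region, seed_smiles, R, T, kappa, eta, L,
               ess_threshold, rng_seed, top_k, tanimoto_threshold, out):
    """Backward prediction: tempered SMC toward a desired property box."""
    lm = LanguageModel.load(lm_path)
    models = [QSPRModel.load(p) for p in qspr.split(",")]
    cfg = SMCConfig(
        region=PropertyRegion.parse(region),
        seeds=tuple(s.strip() for s in seed_smiles.split(",")),
        R=R, T=T, kappa=kappa, eta=eta, L=L,
        ess_threshold=ess_threshold, seed=rng_seed,
    )
    trace = design(cfg, lm, models)
    out.mkdir(parents=True, exist_ok=True)
    trace.to_frame().to_csv(out / "trace.csv", index=False)
    final = trace.records[-1]
    write_smiles_file(out / "final_population.smi", [s for s in final.smiles if s])
    top = trace.top_molecules(top_k, tanimoto_threshold)
    pd.DataFrame(top, columns=["smiles", "likelihood"]).to_csv(out / "top.csv", index=False)
    _write_manifest(out / "manifest.json", "design",
                    {"lm": str(lm_path), "qspr": qspr, "region": region,
                     "seed_smiles": seed_smiles, "R": R, "T": T, "kappa": kappa,
                     "eta": eta, "L": L, "ess_threshold": ess_threshold,
                     "rng_seed": rng_seed})
    click.echo(f"design finished: {T} iterations -> {out}")
    for smi, lik in top:
        click.echo(f"  {lik:.4g}\t{smi}")


def main(argv=None) -> int:
    """Entry point with conventional exit codes (2 usage, 1 runtime failure)."""
    try:
        cli.main(args=argv, standalone_mode=False)
    except click.exceptions.UsageError as exc:
        click.echo(f"usage error: {exc}", err=True)
        return 2
    except click.exceptions.Abort:
        return 1
    except click.exceptions.ClickException as exc:
        exc.show()
        return 1
    except Exception:  # noqa: BLE001 - CLI boundary
        logger.exception("command failed")
        return 1
    return 0


if __name__ == "__main__":  # pragma: no cover
    sys.exit(main())
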