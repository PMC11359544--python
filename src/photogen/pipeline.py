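"""End-to-end workflow: tokenize -> fine-tune -> generate -> predict ->
screen -> criteria -> feedback -> align -> evaluate.

A run is driven by a single YAML config, executes its stages in order into a
run directory, persists every stage artifact, and can resume: a stage whose
artifact already exists is skipped unless explicitly listed in ``stages``.
Unknown config keys are rejected so typos cannot silently change a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem_graph, rlhf, screening, synthetic
from .excitation import ExcitationRegressor, ev_to_nm
from .language_model import (AdapterConfig, GptConfig, GptLM, TrainSchedule,
                             finetune_clm, sample_smiles)
from .tokenizer import SmilesBpeTokenizer

log = logging.getLogger("photogen")

STAGES = ("corpus", "tokenizer", "finetune", "generate", "predict",
          "screen", "feedback", "align", "evaluate")

_DEFAULTS = {
    "seed": 0,
    "out_dir": "run",
    "stages": list(STAGES),
    "corpus": {"n_molecules": 300, "positive_fraction": 0.5, "noise_sd": 0.3,
               "path": None},
    "tokenizer": {"max_merges": 200},
    "model": {"d_model": 64, "n_heads": 4, "n_blocks": 2, "max_positions": 64,
              "adapter_rank": 8, "adapter_alpha": 16.0},
    "finetune": {"epochs": 20, "batch_size": 32, "lr_initial": 5e-4,
                 "lr_final": 5e-8, "trainable": "all"},
    "generate": {"n": 200, "temperature": 1.0, "max_len": 48},
    "predict": {"kernel": "rbf", "C": 80.0, "gamma": 0.84, "max_atoms": 25},
    "screen": {"top_qed": 9, "sascore_window": None},
    "align": {"algorithm": "dpo", "beta": 0.1, "n_steps": 60, "lr": 1e-3,
              "batch_size": 16, "nll_weight": 1.0,
              "desirable_weight": 1.0, "undesirable_weight": 1.0},
    "evaluate": {"n": 200, "temperature": 1.0},
}


def _merge_config(user: dict) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _DEFAULTS.items()}
    for key, val in (user or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config key: {key!r}")
        if isinstance(cfg[key], dict):
            for sub, sval in val.items():
                if sub not in cfg[key]:
                    raise ValueError(f"unknown config key: {key}.{sub}")
                cfg[key][sub] = sval
        else:
            cfg[key] = val
    bad = set(cfg["stages"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    return cfg


@dataclass
class RunResult:
    out_dir: Path
    metrics: dict = field(default_factory=dict)


def load_config(path) -> dict:
    return _merge_config(yaml.safe_load(Path(path).read_text()) or {})


def run_pipeline(config: dict | None = None, config_path=None) -> RunResult:
    """Execute the workflow stages described by ``config`` into a run
    directory; completed stages (artifact present) are not recomputed."""
    if config_path is not None:
        cfg = load_config(config_path)
    else:
        cfg = _merge_config(config or {})
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    seed = int(cfg["seed"])
    stages = set(cfg["stages"])
    metrics_path = out / "metrics.json"
    metrics = json.loads(metrics_path.read_text()) if metrics_path.exists() else {}

    def wants(stage, artifact: Path) -> bool:
        return stage in stages or not artifact.exists()

    # -- corpus ------------------------------------------------------------
    corpus_csv = out / "corpus.csv"
    if wants("corpus", corpus_csv):
        c = cfg["corpus"]
        if c["path"]:
            df = pd.read_csv(c["path"], comment="#")
        else:
            spec = synthetic.FixtureSpec(
                n_molecules=c["n_molecules"], positive_fraction=c["positive_fraction"],
                noise_sd=c["noise_sd"], seed=seed)
            df = pd.DataFrame(synthetic.generate_corpus(spec),
                              columns=["smiles", "energy_eV"])
        df.to_csv(corpus_csv, index=False)
        metrics["corpus"] = {"n": len(df)}
        log.info("corpus: %d molecules", len(df))
    corpus = pd.read_csv(corpus_csv)

    # -- tokenizer ---------------------------------------------------------
    tok_dir = out / "tokenizer"
    if wants("tokenizer", tok_dir / "vocab.txt"):
        tok = SmilesBpeTokenizer(max_merges=cfg["tokenizer"]["max_merges"])
        tok.fit(corpus["smiles"].tolist())
        tok.save(tok_dir)
        metrics["tokenizer"] = {"vocab_size": tok.vocab_size,
                                "n_merges": len(tok.merges)}
    tok = SmilesBpeTokenizer.load(tok_dir)

    # -- finetune ----------------------------------------------------------
    model_path = out / "model.npz"
    m = cfg["model"]
    if wants("finetune", model_path):
        gcfg = GptConfig(vocab_size=tok.vocab_size, d_model=m["d_model"],
                         n_heads=m["n_heads"], n_blocks=m["n_blocks"],
                         max_positions=m["max_positions"])
        model = GptLM(gcfg, seed=seed,
                      adapter_config=AdapterConfig(rank=m["adapter_rank"],
                                                   alpha=m["adapter_alpha"]))
        ids, _ = tok.encode_batch(corpus["smiles"].tolist(),
                                  max_len=m["max_positions"])
        f = cfg["finetune"]
        sched = TrainSchedule(epochs=f["epochs"], batch_size=f["batch_size"],
                              lr_initial=f["lr_initial"], lr_final=f["lr_final"],
                              max_seq_len=m["max_positions"], seed=seed)
        trace = finetune_clm(model, ids, sched, tok.pad_id, trainable=f["trainable"])
        model.save(model_path)
        metrics["finetune"] = {"loss_trace": trace}
        log.info("finetune: loss %.4f -> %.4f", trace[0], trace[-1])
    model = GptLM.load(model_path)

    # -- generate ----------------------------------------------------------
    gen_smi = out / "generated.smi"
    if wants("generate", gen_smi):
        g = cfg["generate"]
        report = sample_smiles(model, tok, n=g["n"], seed=seed + 1,
                               temperature=g["temperature"], max_len=g["max_len"])
        chem_graph.write_smiles_file(gen_smi, report.smiles, header=f"seed={seed + 1}")
        metrics["generate"] = {"n": report.n, "n_valid": report.n_valid,
                               "n_unique_valid": report.n_unique_valid}
        log.info("generate: %d/%d valid", report.n_valid, report.n)
    generated = chem_graph.read_smiles_file(gen_smi)
    valid_graphs = {}
    for s in generated:
        gph = chem_graph.parse_smiles(s)
        if isinstance(gph, chem_graph.MoleculeGraph):
            valid_graphs.setdefault(gph.canonical_smiles, gph)

    # -- predict -----------------------------------------------------------
    pred_csv = out / "predicted.csv"
    if wants("predict", pred_csv):
        p = cfg["predict"]
        feats, energies, _, _ = synthetic.featurized_dataset(
            synthetic.FixtureSpec(
                n_molecules=cfg["corpus"]["n_molecules"],
                positive_fraction=cfg["corpus"]["positive_fraction"],
                noise_sd=cfg["corpus"]["noise_sd"], seed=seed),
            max_atoms=p["max_atoms"])
        reg = ExcitationRegressor(kernel=p["kernel"], C=p["C"], gamma=p["gamma"],
                                  split_seed=seed).fit(feats, energies)
        rows = []
        rng = np.random.default_rng(seed + 2)
        from .excitation import coulomb_matrix, featurize

        for smi, gph in valid_graphs.items():
            got = synthetic.coordinates_for(gph, seed=int(rng.integers(2**31 - 1)))
            if got is None or len(got[0]) > p["max_atoms"]:
                continue
            x = featurize(coulomb_matrix(got[0], got[1], p["max_atoms"]))
            e = float(reg.predict([x])[0])
            rows.append({"smiles": smi, "predicted_eV": e,
                         "predicted_nm": ev_to_nm(max(e, 1e-6))})
        pd.DataFrame(rows, columns=["smiles", "predicted_eV", "predicted_nm"]
                     ).to_csv(pred_csv, index=False)
        metrics["predict"] = {"train_mse": reg.train_mse_, "test_mse": reg.test_mse_,
                              "n_predicted": len(rows)}
        log.info("predict: train MSE %.3f, test MSE %.3f", reg.train_mse_, reg.test_mse_)
    predicted = pd.read_csv(pred_csv)

    # -- screen ------------------------------------------------------------
    screen_csv = out / "screened.csv"
    if wants("screen", screen_csv):
        s = cfg["screen"]
        nm_map = dict(zip(predicted["smiles"], predicted["predicted_nm"]))
        smiles = list(valid_graphs)
        scored = screening.score_molecules(
            smiles, [nm_map.get(x) for x in smiles])
        scored.to_csv(screen_csv, index=False)
        top = screening.rank_select(scored, key="qed", k=s["top_qed"])
        top.to_csv(out / "top_qed.csv", index=False)
        if s["sascore_window"]:
            screening.rank_select(scored, sascore_window=tuple(s["sascore_window"])
                                  ).to_csv(out / "sascore_selected.csv", index=False)
        metrics["screen"] = {"n_scored": len(scored),
                             "qed_max": float(scored["qed"].max()) if len(scored) else None}
    scored = pd.read_csv(screen_csv)

    # -- feedback ----------------------------------------------------------
    pref_jsonl, kto_jsonl = out / "preference.jsonl", out / "binary.jsonl"
    if wants("feedback", pref_jsonl):
        verdicts = {s: chem_graph.evaluate_criteria(g) for s, g in valid_graphs.items()}
        pairs, binary = rlhf.build_feedback(verdicts, seed=seed)
        rlhf.write_jsonl(pref_jsonl, pairs)
        rlhf.write_jsonl(kto_jsonl, binary)
        metrics["feedback"] = {"n_pairs": len(pairs), "n_binary": len(binary)}
        log.info("feedback: %d pairs, %d binary", len(pairs), len(binary))

    # -- align -------------------------------------------------------------
    aligned_path = out / "model_aligned.npz"
    a = cfg["align"]
    if wants("align", aligned_path):
        dataset = rlhf.read_jsonl(kto_jsonl if a["algorithm"] == "kto" else pref_jsonl)
        rcfg = rlhf.RlhfConfig(algorithm=a["algorithm"], beta=a["beta"],
                               nll_weight=a["nll_weight"], lr=a["lr"],
                               n_steps=a["n_steps"], batch_size=a["batch_size"],
                               desirable_weight=a["desirable_weight"],
                               undesirable_weight=a["undesirable_weight"], seed=seed)
        aligned = model.clone()
        res = rlhf.rlhf_finetune(aligned, tok, dataset, rcfg)
        aligned.save(aligned_path)
        metrics["align"] = {"algorithm": a["algorithm"],
                            "loss_first": res.loss_trace[0],
                            "loss_last": res.loss_trace[-1]}
        log.info("align[%s]: loss %.4f -> %.4f", a["algorithm"],
                 res.loss_trace[0], res.loss_trace[-1])

    # -- evaluate ----------------------------------------------------------
    if "evaluate" in stages or "evaluation" not in metrics:
        aligned = GptLM.load(aligned_path)
        e = cfg["evaluate"]
        rep = sample_smiles(aligned, tok, n=e["n"], seed=seed + 3,
                            temperature=e["temperature"])
        n_valid, n_pass, ratio = rlhf.evaluate_generation(rep.smiles)
        chem_graph.write_smiles_file(out / "aligned_samples.smi", rep.smiles,
                                     header=f"seed={seed + 3}")
        metrics["evaluation"] = {"n_sampled": rep.n, "n_valid": n_valid,
                                 "n_weakened_pass": n_pass,
                                 "ratio_percent": ratio}
        log.info("evaluate: %s/%s weakened-pass (%.2f%%)", n_pass, n_valid,
                 ratio if ratio is not None else float("nan"))

    metrics_path.write_text(json.dumps(metrics, indent=2))
    return RunResult(out_dir=out, metrics=metrics)
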