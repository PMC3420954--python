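"""End-to-end orchestration of the four analyses on one input bundle.

Stages: (1) ancestral-state reconstruction of the binary trait and
comparison of origin-number models; (2) the pairwise onset (delta) report;
(3) molecular-clock dating of sequence pairs; (4) the complexity
regression.  Outputs are plain delimited text plus a JSON run manifest
recording the seed, package version, and SHA-256 digests of inputs and
outputs, so a rerun with the same configuration is byte-identical.

Each stochastic stage draws its seed from the root seed through a named
substream, so stages can be re-run in isolation without perturbing the
others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, complexity, divergence, hypotheses, io, mk2, onset, trees

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]

log = logging.getLogger("eyespot_origins")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    tree_path: str | None = None
    character_path: str | None = None
    models_path: str | None = None
    onset_path: str | None = None
    onset_pairs: list[tuple[str, str]] = field(default_factory=list)
    fasta_path: str | None = None
    species_of: dict[str, str] = field(default_factory=dict)  #: seq id -> species
    complexity_path: str | None = None
    root_prior: str = "stationary"
    n_restarts: int = 5
    n_boot: int = 1000
    clock_rate: float = divergence.DEFAULT_CLOCK_RATE
    seed: int = 0
    out_dir: str = "results"


def _substream(root_seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; return the manifest dictionary.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of earlier stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "inputs": {},
        "outputs": {},
        "stages": [],
    }
    for name in ("tree_path", "character_path", "models_path", "onset_path",
                 "fasta_path", "complexity_path"):
        p = getattr(config, name)
        if p is not None:
            path = Path(p)
            if not path.exists():
                raise PipelineError(name.replace("_path", ""), FileNotFoundError(p))
            manifest["inputs"][name] = _sha256(path)

    def record(stage: str, filename: str, text: str) -> None:
        path = out / filename
        path.write_text(text)
        manifest["outputs"][filename] = _sha256(path)
        manifest["stages"].append(stage)
        log.info("stage %s -> %s", stage, path)

    # --- origins: ancestral states + model comparison ------------------
    if config.tree_path and config.character_path:
        try:
            tree = trees.read_newick(Path(config.tree_path).read_text())
            char = io.read_character(config.character_path)
            fit = mk2.fit_rates(
                tree, char, None, config.root_prior,
                config.n_restarts, _substream(config.seed, "fit"),
            )
            log.info("unconstrained fit: gain=%.6g loss=%.6g lnL=%.4f (%d restarts)",
                     fit.rates.gain, fit.rates.loss, fit.lnL, fit.n_restarts_used)
            anc = mk2.marginal_ancestral_states(
                tree, char, fit.rates, config.root_prior
            )
            lines = ["node\tage_my\tp0\tp1"]
            for node, (p0, p1) in sorted(anc.items()):
                age = trees.node_age(tree, node) if tree.is_ultrametric() else float("nan")
                lines.append(f"{node}\t{age:.6g}\t{p0:.9f}\t{p1:.9f}")
            record("ancestral_states", "ancestral_states.tsv", "\n".join(lines) + "\n")
            counts = hypotheses.count_origins(tree, anc, char)
            record(
                "origin_count", "origin_count.tsv",
                "min_origins\tmax_origins\troot_stem_origin\n"
                f"{counts.min_count}\t{counts.max_count}\t{counts.root_stem_origin}\n",
            )
            if config.models_path:
                models = hypotheses.read_model_file(tree, config.models_path)
                table = hypotheses.evaluate_models(
                    tree, char, models, root_prior=config.root_prior,
                    n_restarts=config.n_restarts,
                    seed=_substream(config.seed, "models"),
                )
                record("origin_models", "origin_models.tsv",
                       table.to_csv(sep="\t", index=False, float_format="%.6f"))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("origins", exc) from exc

    # --- onset ----------------------------------------------------------
    if config.onset_path:
        try:
            data = io.read_onset(config.onset_path)
            pairs = config.onset_pairs
            if not pairs:
                genes = sorted(set(data["gene"]))
                pairs = list(zip(genes[:-1], genes[1:]))
            report = onset.pairwise_onset_report(
                data, pairs, n_boot=config.n_boot,
                seed=_substream(config.seed, "onset"),
            )
            record("onset", "onset_report.tsv",
                   report.to_csv(sep="\t", index=False, float_format="%.6f"))
        except Exception as exc:
            raise PipelineError("onset", exc) from exc

    # --- divergence dating ----------------------------------------------
    if config.fasta_path:
        try:
            seqs = divergence.read_fasta(config.fasta_path)
            by_species: dict[str, list[str]] = {}
            for sid, seq in seqs.items():
                sp = config.species_of.get(sid, sid)
                by_species.setdefault(sp, []).append(seq)
            names = sorted(by_species)
            lines = ["species_a\tspecies_b\tpercent_divergence\ttime_mya"]
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    d = divergence.mean_between_species_divergence(
                        by_species[a], by_species[b]
                    )
                    est = divergence.divergence_time(d, config.clock_rate)
                    lines.append(f"{a}\t{b}\t{d:.4f}\t{est.time_mya:.2f}")
            record("divergence", "clock_estimates.tsv", "\n".join(lines) + "\n")
        except Exception as exc:
            raise PipelineError("divergence", exc) from exc

    # --- complexity regression ------------------------------------------
    if config.complexity_path:
        try:
            records = io.read_complexity(config.complexity_path)
            res = complexity.complexity_regression(records)
            record(
                "complexity", "complexity_regression.tsv",
                "slope\tintercept\tF\tdf1\tdf2\tp\tr_squared\n"
                f"{res.slope:.6f}\t{res.intercept:.6f}\t{res.f_statistic:.6f}\t"
                f"{res.df[0]}\t{res.df[1]}\t{res.p_value:.6f}\t{res.r_squared:.6f}\n",
            )
        except Exception as exc:
            raise PipelineError("complexity", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
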