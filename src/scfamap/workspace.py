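"""Demo-workspace writer: one call emits every flat file the pipeline reads.

The workspace contains, for a single seeded synthetic community:

- ``registry.yaml``        pathway registry (self-contained copy)
- ``hits.tsv``             per-genome homology hits (classification input)
- ``genes.fasta``          per-genome pathway-gene sequences (``genome|gene`` ids)
- ``rplb.fasta`` / ``rplb_scores.tsv``  rplB candidates with qualifying scores
- ``abundances.tsv``       species relative abundances with taxonomy
- ``phenotypes.tsv``       literature-style fermentation phenotypes
- ``counts.tsv`` / ``rplb_counts.tsv``  per-sample mapped-read counts (long format)
- ``truth.tsv``            the generating genotype truth, for reference
- ``manifest.json``        provenance stamp
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .manifest import write_manifest
from .schema import PathwayRegistry, load_registry
from .simulate import (
    CommunityTruth,
    SimulationConfig,
    simulate_community,
    simulate_hits,
    simulate_phenotypes,
    simulate_sample_counts,
)

__all__ = ["write_demo_workspace"]

PHENOTYPE_ERROR_RATE = 0.05
PHENOTYPE_UNKNOWN_RATE = 0.25


def write_demo_workspace(
    out_dir: str | Path,
    config: SimulationConfig,
    registry: PathwayRegistry | None = None,
) -> CommunityTruth:
    """Simulate a community and write a complete, self-contained workspace.

    Deterministic for a fixed ``config``: rerunning into a fresh directory
    reproduces every file byte-for-byte (the manifest differs only in its
    timestamp).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = registry if registry is not None else load_registry()

    truth = simulate_community(config, registry)
    registry.to_yaml(out / "registry.yaml")
    truth.truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.10g")
    truth.abundance_table.to_csv(
        out / "abundances.tsv", sep="\t", index=False, float_format="%.10g"
    )
    truth.truth[["genome", "species"]].to_csv(
        out / "species_map.tsv", sep="\t", index=False
    )

    hits = simulate_hits(truth, seed=config.seed + 1)
    pd.DataFrame(
        [
            {
                "genome": h.genome_id,
                "gene": h.gene,
                "subject": h.subject_id,
                "score": h.score,
                "length": h.length,
                "description": h.description,
            }
            for h in hits
        ]
    ).to_csv(out / "hits.tsv", sep="\t", index=False)

    SeqIO.write(
        (
            SeqRecord(Seq(seq), id=f"{genome}|{gene}", description="")
            for (genome, gene), seq in sorted(truth.gene_sequences.items())
        ),
        str(out / "genes.fasta"),
        "fasta",
    )
    SeqIO.write(
        (
            SeqRecord(Seq(seq), id=genome, description="")
            for genome, seq, _score in truth.rplb_records
        ),
        str(out / "rplb.fasta"),
        "fasta",
    )
    pd.DataFrame(
        [{"genome": g, "score": round(s, 1)} for g, _seq, s in truth.rplb_records]
    ).to_csv(out / "rplb_scores.tsv", sep="\t", index=False)

    simulate_phenotypes(
        truth,
        error_rate=PHENOTYPE_ERROR_RATE,
        unknown_rate=PHENOTYPE_UNKNOWN_RATE,
        seed=config.seed + 2,
    ).to_csv(out / "phenotypes.tsv", sep="\t", index=False)

    rng = np.random.default_rng(config.seed + 3)
    count_rows, rplb_rows = [], []
    for i in range(config.n_samples):
        sample = f"S{i + 1:02d}"
        counts = simulate_sample_counts(truth, sample, rng)
        count_rows.extend(
            {"sample": sample, "entry": e, "count": int(c)}
            for e, c in sorted(counts.gene_counts.items())
        )
        rplb_rows.extend(
            {"sample": sample, "entry": e, "count": int(c)}
            for e, c in sorted(counts.rplb_counts.items())
        )
    pd.DataFrame(count_rows, columns=["sample", "entry", "count"]).to_csv(
        out / "counts.tsv", sep="\t", index=False
    )
    pd.DataFrame(rplb_rows, columns=["sample", "entry", "count"]).to_csv(
        out / "rplb_counts.tsv", sep="\t", index=False
    )

    write_manifest(
        out,
        command="simulate",
        seed=config.seed,
        config=config.__dict__ | {"carriage": dict(config.carriage)},
    )
    return truth
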