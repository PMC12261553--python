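"""End-to-end pipeline: simulate -> cohort -> encode -> align -> cluster -> report.

All randomness derives from the configuration seed, so two runs with the
same configuration write byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cluster import (
    ClusterSolution,
    select_num_clusters,
    similarity_to_distance,
    write_solution,
)
from .cohort import CohortMember, select_als_cohort, write_cohort
from .datasets import ClaimsDataset
from .encode import PathwaySequence, encode_cohort, write_sequences
from .quality import cluster_quality_table, write_quality_report
from .synthetic import SimulationConfig, generate_claims
from .tnw import TNWParams, pairwise_similarity_matrix

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    claims: ClaimsDataset
    cohort: list[CohortMember]
    sequences: list[PathwaySequence]
    similarity: pd.DataFrame
    distance: pd.DataFrame
    solution: ClusterSolution
    quality_table: pd.DataFrame


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    params: TNWParams = TNWParams(),
    k_min: int = 2,
    k_max: int = 8,
    B: int = 50,
    linkage_method: str = "average",
) -> PipelineResult:
    """Run the full analysis on one synthetic draw.

    When ``out_dir`` is given, every stage writes its standard files there
    (claims CSVs, cohort.csv/table1.csv, sequences.csv/graph.json,
    similarity.csv/distance.csv, clusters.csv/stability.csv/dendrogram.nwk,
    table2.csv/table2.md).  The clustering seed is derived from the
    simulation seed, so the whole run is a function of the config alone.
    """
    claims = generate_claims(config)
    cohort = select_als_cohort(claims)
    sequences = encode_cohort(cohort)
    similarity = pairwise_similarity_matrix(sequences, params)
    distance = similarity_to_distance(similarity)
    solution = select_num_clusters(
        distance, k_min=k_min, k_max=k_max, B=B,
        seed=config.seed, linkage_method=linkage_method,
    )
    table = cluster_quality_table(cohort, solution.labels)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        claims.write(out)
        write_cohort(cohort, out)
        write_sequences(sequences, out)
        similarity.to_csv(out / "similarity.csv")
        distance.to_csv(out / "distance.csv")
        write_solution(solution, out)
        write_quality_report(table, out)

    return PipelineResult(
        claims=claims,
        cohort=cohort,
        sequences=sequences,
        similarity=similarity,
        distance=distance,
        solution=solution,
        quality_table=table,
    )
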