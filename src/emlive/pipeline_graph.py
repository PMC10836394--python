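"""The job graph of a RELION project, read from ``pipeline.star``.

A project pipeline is bipartite: *jobs* (processes such as
``MotionCorr/job002/``) produce and consume *data nodes* (files such as
``MotionCorr/job002/corrected_micrographs.star``).  Output edges connect
a job to the files it writes; input edges connect a file to the jobs
that read it.  The induced job-level graph — job A precedes job B iff A
outputs a file B consumes — must be acyclic.

Job types and statuses are open vocabularies passed through verbatim,
so job types introduced by future RELION versions are read without code
changes.  The exact block and label spellings of the on-disk dialect are
confined to the ``DIALECT`` table below; supporting a renamed dialect is
a one-line change there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import networkx as nx

from .star_io import (
    LoopTable,
    StarBlock,
    StarDocument,
    StarLookupError,
    format_value,
    read_star,
)

__all__ = [
    "JobNode",
    "PipelineGraph",
    "PipelineError",
    "DIALECT",
    "parse_pipeline",
    "read_pipeline",
    "pipeline_to_star",
    "job_edges",
    "topological_order",
    "job_parameters",
]


class PipelineError(ValueError):
    pass


# RELION 4 pipeline.star dialect; renames in later versions go here.
DIALECT = {
    "processes_block": "pipeline_processes",
    "nodes_block": "pipeline_nodes",
    "input_edges_block": "pipeline_input_edges",
    "output_edges_block": "pipeline_output_edges",
    "process_name": "_rlnPipeLineProcessName",
    "process_alias": "_rlnPipeLineProcessAlias",
    "process_type": "_rlnPipeLineProcessTypeLabel",
    "process_status": "_rlnPipeLineProcessStatusLabel",
    "node_name": "_rlnPipeLineNodeName",
    "node_type": "_rlnPipeLineNodeTypeLabel",
    "edge_from_node": "_rlnPipeLineEdgeFromNode",
    "edge_process": "_rlnPipeLineEdgeProcess",
    "edge_to_node": "_rlnPipeLineEdgeToNode",
    "job_block": "job",
    "joboptions_block": "joboptions_values",
    "joboption_variable": "_rlnJobOptionVariable",
    "joboption_value": "_rlnJobOptionValue",
}

NO_ALIAS = "None"


@dataclass(frozen=True)
class JobNode:
    """One processing job; ``name`` ends with '/' per RELION convention."""

    name: str
    type: str = ""
    status: str = ""
    alias: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name.endswith("/"):
            raise PipelineError(f"job name must end with '/': {self.name!r}")


@dataclass
class PipelineGraph:
    """Jobs, data files and the producer/consumer edges between them."""

    jobs: List[JobNode] = field(default_factory=list)
    data_nodes: List[str] = field(default_factory=list)
    # (job name, data node): job wrote that file
    output_edges: List[Tuple[str, str]] = field(default_factory=list)
    # (data node, job name): job reads that file
    input_edges: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [j.name for j in self.jobs]
        if len(set(names)) != len(names):
            raise PipelineError(f"duplicate job names: {names}")
        job_set = set(names)
        node_set = set(self.data_nodes)
        for job, node in self.output_edges:
            if job not in job_set:
                raise PipelineError(f"output edge from unknown job {job!r}")
            if node not in node_set:
                raise PipelineError(f"output edge to unknown data node {node!r}")
        for node, job in self.input_edges:
            if job not in job_set:
                raise PipelineError(f"input edge to unknown job {job!r}")
            if node not in node_set:
                raise PipelineError(f"input edge from unknown data node {node!r}")
        cycle = _find_job_cycle(self)
        if cycle:
            raise PipelineError(f"job graph contains a cycle: {' -> '.join(cycle)}")

    def job(self, name: str) -> JobNode:
        for j in self.jobs:
            if j.name == name or j.alias == name:
                return j
        raise PipelineError(
            f"job {name!r} not found; available: {[j.name for j in self.jobs]}"
        )

    def producers_of(self, data_node: str) -> List[str]:
        return [j for j, n in self.output_edges if n == data_node]

    def consumers_of(self, data_node: str) -> List[str]:
        return [j for n, j in self.input_edges if n == data_node]

    def inputs_of(self, job_name: str) -> List[str]:
        return [n for n, j in self.input_edges if j == job_name]

    def outputs_of(self, job_name: str) -> List[str]:
        return [n for j, n in self.output_edges if j == job_name]


def _job_graph(graph: PipelineGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(j.name for j in graph.jobs)
    for producer, consumer in job_edges_unchecked(graph):
        g.add_edge(producer, consumer)
    return g


def _find_job_cycle(graph: PipelineGraph) -> Optional[List[str]]:
    g = _job_graph(graph)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return [edge[0] for edge in cycle] + [cycle[-1][1]]


def job_edges_unchecked(graph: PipelineGraph) -> List[Tuple[str, str]]:
    pairs = set()
    consumers: Dict[str, List[str]] = {}
    for node, job in graph.input_edges:
        consumers.setdefault(node, []).append(job)
    for producer, node in graph.output_edges:
        for consumer in consumers.get(node, []):
            # a job consuming its own output is a self-loop and is rejected
            # by the acyclicity invariant at graph construction
            pairs.add((producer, consumer))
    return sorted(pairs)


def job_edges(graph: PipelineGraph) -> List[Tuple[str, str]]:
    """Deduplicated producer→consumer job pairs, sorted by (producer, consumer).

    Two jobs are connected iff at least one data node is output by the
    first and input to the second.
    """
    return job_edges_unchecked(graph)


def topological_order(graph: PipelineGraph) -> List[str]:
    """Job names with every producer before its consumers; ties by name."""
    g = _job_graph(graph)
    return list(nx.lexicographical_topological_sort(g))


def parse_pipeline(doc: StarDocument) -> PipelineGraph:
    """Build a :class:`PipelineGraph` from a parsed ``pipeline.star``.

    Edges referencing a process or data node that is not declared raise
    :class:`PipelineError` naming the dangling reference.
    """
    d = DIALECT
    jobs: List[JobNode] = []
    if doc.has_block(d["processes_block"]):
        block = doc.get_block(d["processes_block"])
        if block.table is not None:
            names = block.table.column(d["process_name"])
            types = block.table.column(d["process_type"])
            statuses = block.table.column(d["process_status"])
            try:
                aliases = block.table.column(d["process_alias"])
            except StarLookupError:
                aliases = [NO_ALIAS] * len(names)
            for name, alias, typ, status in zip(names, aliases, types, statuses):
                jobs.append(
                    JobNode(
                        name=str(name),
                        alias=None if alias == NO_ALIAS else str(alias),
                        type=str(typ),
                        status=str(status),
                    )
                )
    data_nodes: List[str] = []
    if doc.has_block(d["nodes_block"]):
        block = doc.get_block(d["nodes_block"])
        if block.table is not None:
            data_nodes = [str(x) for x in block.table.column(d["node_name"])]

    job_names = {j.name for j in jobs}
    node_names = set(data_nodes)

    def _check(kind: str, job: str, node: str) -> None:
        if job not in job_names:
            raise PipelineError(f"{kind} edge references unknown process {job!r}")
        if node not in node_names:
            raise PipelineError(f"{kind} edge references unknown data node {node!r}")

    input_edges: List[Tuple[str, str]] = []
    if doc.has_block(d["input_edges_block"]):
        block = doc.get_block(d["input_edges_block"])
        if block.table is not None:
            froms = block.table.column(d["edge_from_node"])
            procs = block.table.column(d["edge_process"])
            for node, job in zip(froms, procs):
                _check("input", str(job), str(node))
                input_edges.append((str(node), str(job)))
    output_edges: List[Tuple[str, str]] = []
    if doc.has_block(d["output_edges_block"]):
        block = doc.get_block(d["output_edges_block"])
        if block.table is not None:
            procs = block.table.column(d["edge_process"])
            tos = block.table.column(d["edge_to_node"])
            for job, node in zip(procs, tos):
                _check("output", str(job), str(node))
                output_edges.append((str(job), str(node)))
    return PipelineGraph(
        jobs=jobs,
        data_nodes=data_nodes,
        output_edges=output_edges,
        input_edges=input_edges,
    )


def read_pipeline(path) -> PipelineGraph:
    return parse_pipeline(read_star(path))


def pipeline_to_star(graph: PipelineGraph) -> StarDocument:
    """Serialize a graph back to the pipeline.star dialect (round-trippable)."""
    d = DIALECT
    proc_rows = [
        (j.name, j.alias if j.alias is not None else NO_ALIAS, j.type, j.status)
        for j in graph.jobs
    ]
    blocks = [
        StarBlock(
            name="pipeline_general",
            pairs={"_rlnPipeLineJobCounter": len(graph.jobs) + 1},
        ),
        StarBlock(
            name=d["processes_block"],
            table=LoopTable(
                [d["process_name"], d["process_alias"], d["process_type"],
                 d["process_status"]],
                proc_rows,
            ),
        ),
        StarBlock(
            name=d["nodes_block"],
            table=LoopTable(
                [d["node_name"], d["node_type"]],
                [(n, _guess_node_type(n)) for n in graph.data_nodes],
            ),
        ),
        StarBlock(
            name=d["input_edges_block"],
            table=LoopTable(
                [d["edge_from_node"], d["edge_process"]],
                list(graph.input_edges),
            ),
        ),
        StarBlock(
            name=d["output_edges_block"],
            table=LoopTable(
                [d["edge_process"], d["edge_to_node"]],
                list(graph.output_edges),
            ),
        ),
    ]
    return StarDocument(blocks)


def _guess_node_type(node_name: str) -> str:
    suffix = Path(node_name).suffix.lstrip(".")
    return f"{suffix or 'file'}"


def job_parameters(project_root, job: JobNode) -> Dict[str, str]:
    """The job's parameters, in the order ``job.star`` lists them.

    Values are returned in text form: booleans stay ``Yes``/``No``,
    paths stay verbatim, numbers render in the standard column format.
    Jobs predating the RELION 4 per-job ``job.star`` layout raise
    :class:`StarLookupError`.
    """
    path = Path(project_root) / job.name / "job.star"
    if not path.exists():
        raise StarLookupError(
            f"no job.star for {job.name!r} (looked at {path}); "
            "the job may predate the RELION 4 layout"
        )
    doc = read_star(path)
    d = DIALECT
    block = doc.get_block(d["joboptions_block"])
    if block.table is None or block.table.n_rows == 0:
        return {}
    variables = block.table.column(d["joboption_variable"])
    values = block.table.column(d["joboption_value"])
    return {
        str(var): (val if isinstance(val, str) else format_value(val))
        for var, val in zip(variables, values)
    }
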