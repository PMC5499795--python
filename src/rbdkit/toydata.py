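"""Built-in synthetic toy domain set.

Six entries with annotations typical of RNA-binding domain families (RRM,
KH, cold-shock, S1, CsrA-like, ProQ/FinO) plus two non-RNA decoys (kinase,
periplasmic transporter). The consensus sequences are SYNTHETIC — random
sequences drawn once from a fixed seed, NOT real family consensuses — so
the set exercises keyword selection, scanning, filtering and scoring
without shipping any database content.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .chemdata import AA20
from .refdomains import DomainEntry

_SPECS = [
    # (domain_id, accession, short_name, description, length, go_terms)
    ("TD001", "TOY00001", "RRM_like", "RNA recognition motif, RNA-binding domain",
     70, ["GO:0003723 RNA binding"]),
    ("TD002", "TOY00002", "KH_like", "KH domain, RNA-binding",
     60, ["GO:0003723 RNA binding"]),
    ("TD003", "TOY00003", "CSD_like", "Cold shock domain, nucleic-acid binding",
     65, ["GO:0003676 nucleic acid binding"]),
    ("TD004", "TOY00004", "S1_like", "S1 RNA-binding ribosomal protein domain",
     68, ["GO:0003723 RNA binding"]),
    ("TD005", "TOY00005", "CsrA_like", "Carbon storage regulator, RNA-binding",
     58, ["GO:0003723 RNA binding"]),
    ("TD006", "TOY00006", "ProQ_like", "ProQ/FinO family RNA chaperone domain",
     76, ["GO:0003723 RNA binding"]),
    ("TD007", "TOY00007", "PK_like", "Protein kinase catalytic domain",
     72, ["GO:0016301 kinase activity"]),
    ("TD008", "TOY00008", "ABC_peri", "Periplasmic ABC transporter binding domain",
     64, []),
]

_SEED = 20170302


def toy_domains() -> list[DomainEntry]:
    """The toy set with deterministic synthetic consensus sequences."""
    rng = np.random.default_rng(_SEED)
    entries = []
    for domain_id, acc, name, desc, length, gos in _SPECS:
        consensus = "".join(AA20[i] for i in rng.integers(0, 20, size=length))
        entries.append(DomainEntry(
            source_db="toy", domain_id=domain_id, accession=acc,
            short_name=name, description=desc, length=length,
            consensus=consensus, go_terms=list(gos),
        ))
    return entries


def write_toy_domain_table(path: str | Path) -> None:
    """Write the toy set in the standard domain-table TSV layout."""
    lines = ["#domain_id\taccession\tshort_name\tdescription\tlength\tconsensus\tgo_terms"]
    for e in toy_domains():
        lines.append("\t".join([
            e.domain_id, e.accession, e.short_name, e.description,
            str(e.length), e.consensus or "-", ";".join(e.go_terms),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
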