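import sys
from pathlib import Path

import pytest
from hypothesis import settings as _hypothesis_settings

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles imports

_hypothesis_settings.register_profile("repro", derandomize=True)
_hypothesis_settings.load_profile("repro")

from rbdkit.refdomains import DomainEntry
from rbdkit.toydata import toy_domains


@pytest.fixture(scope="session")
def domains() -> list[DomainEntry]:
    """The built-in synthetic toy domain set (consensus-bearing entries)."""
    return toy_domains()


@pytest.fixture(scope="session")
def rna_domains(domains) -> list[DomainEntry]:
    """The toy entries annotated as RNA/nucleic-acid binding."""
    return [d for d in domains
            if "RNA" in d.description or "nucleic" in d.description]


@pytest.fixture()
def domain_table(tmp_path) -> Path:
    from rbdkit.toydata import write_toy_domain_table

    path = tmp_path / "domains.tsv"
    write_toy_domain_table(path)
    return path
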