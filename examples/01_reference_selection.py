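"""Select a reference domain set by keyword.

Builds the toy domain table, then selects the entries whose annotations
match RNA-binding keywords — including the prefix term "RNA-bind", which
matches "RNA-binding" by substring, and the multi-word term "cold shock",
which requires both words in the same annotation field.
"""

from rbdkit import KeywordSpec, select_domains
from rbdkit.toydata import toy_domains

entries = toy_domains()
keywords = KeywordSpec(terms=["RNA-bind", "cold shock", "RNA chaperone"])
reference = select_domains(entries, keywords)

print(f"{len(reference)} of {len(entries)} domains selected:")
for entry in reference:
    print(f"  {entry.domain_id}  {entry.short_name:10s}  {entry.description}")

# The selected ids form the reference set used to gate domain hits: a
# predicted hit only counts if its domain is one of these.
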