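#!/usr/bin/env python
"""Combine the ACMG evidence observed for the focal variant.

Evidence: PS3 (functional loss of integrin binding), PM2 (absent from
population databases), PP3 (conservation), PP4 (phenotype specificity),
PP5 (prior reputable-source assertion). One strong plus one moderate
criterion fires the likely-pathogenic combining rule.
"""

import json
from pathlib import Path

from founderhap.acmg import classify

RESULTS = Path(__file__).resolve().parent.parent / "results"
TAGS = ("PS3", "PM2", "PP3", "PP4", "PP5")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    result = classify(TAGS)
    print(f"tags {','.join(TAGS)} -> {result.value} (rule {result.fired_rule})")
    for w in result.warnings:
        print(f"warning: {w}")
    doc = {"tags": list(TAGS), **result.to_dict()}
    (RESULTS / "acmg_classification.json").write_text(json.dumps(doc, indent=2) + "\n")


if __name__ == "__main__":
    main()
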