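# External data

The published analyses operate on a facility location table distributed as
supplementary material with the source study (a plain-text delimited file
with columns `type`, `g_lon`, `g_lat`; one row per CMS-certified facility).
It is not redistributed here.

To reproduce the published nationwide and state-level numbers, download
that table and save it as:

    data/s1_facilities.txt

The acceptance tests in `tests/test_acceptance.py` that reference the
published grid, census, and state shares will then run against it; without
the file they fail with a `FileNotFoundError`.  All other tests and all
`analysis/` scripts are self-contained and use synthetic data.
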