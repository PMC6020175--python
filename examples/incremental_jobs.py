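"""Process a document stream in partitioned, incremental jobs.

A job only picks up documents dated after the high-water mark left by the
last successful job, so re-running after success is a no-op and a failed
partition causes its documents to be retried next time.
"""

import tempfile
from pathlib import Path

from phimask import GeneratorConfig, run_job
from phimask.corpus import generate_corpus
from phimask.data_model import write_documents, write_phi_records

workdir = Path(tempfile.mkdtemp())
docs, phis = generate_corpus(GeneratorConfig(n_docs=20, seed=3))
write_documents(docs, workdir / "docs.jsonl")
write_phi_records(phis, workdir / "phis.csv")

state, out = workdir / "state.json", workdir / "masked.jsonl"
first = run_job(workdir / "docs.jsonl", workdir / "phis.csv",
                n_partitions=4, state_path=state, out_path=out)
print(f"first run : {first.status}, {len(out.read_text().splitlines())} documents masked,"
      f" high-water mark {first.high_water_mark}")

second = run_job(workdir / "docs.jsonl", workdir / "phis.csv",
                 n_partitions=4, state_path=state, out_path=out)
print(f"second run: {second.status}, still {len(out.read_text().splitlines())} lines"
      " (nothing newer than the mark)")
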