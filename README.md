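# ehrfrag

Display and task fragmentation metrics for electronic health record (EHR)
user interfaces.

Clinicians reviewing a patient case often find the relevant information —
notes, labs, medications, imaging — scattered across many screens and menu
levels. That *display fragmentation* forces extra navigation and working
memory use, and it splinters clinical tasks into many short, interrupted
bursts (*task fragmentation*). `ehrfrag` is a library + CLI for usability
researchers and informaticists that quantifies both, from two kinds of
input that a usability study produces:

* a **navigation tree** mapped by a modified cognitive walkthrough of the
  interface (a path-per-row CSV or nested JSON), and
* a **session event log** of time-stamped, task-labeled segments from
  screen recordings (CSV).

## The measures

**Display Fragmentation Index (DFI).** Over a measured pathway that visits
every task-relevant (target) element of the navigation tree,

```
DFI = E + IS·X_IS + C·X_C + SS·X_SS + ML
```

where `E` counts the target elements (no multiplier), `IS` intermediate
screen transitions, `C` clicks (every screen transition is also a click),
`SS` scroll actions (a scrolling screen costs 2 per entry), and `ML` the
accumulated menu length at each decision point. `X` weights each action by
the hierarchy level at which it occurs (`depth_weighted`, the default) or
by a constant. The default pathway is a reasonable maximum that returns to
the root between targets; a `shortest` policy ascends only to the lowest
common ancestor.

**ACT and PPI.** A *task instance* is a maximal run of consecutive
same-task log segments. For each task,

```
ACT = task total time / number of instances          (average continuous time)
PPI = task total time / (instances × total EHR time) (proportion per instance)
```

Longer ACT and higher PPI mean less fragmented work; PPI is normalized so
longer sessions do not inflate the measure (PPI = ACT / total EHR time).

Both measures pair with a visualization: **sunburst** maps (concentric
rings = hierarchy levels, dark sectors = targets, green = a traced
pathway) and **time belts** (one row per session, color-coded
duration-proportional task bars). The report layer also detects
**pogo-sticking** — repeated back-and-forth alternation between two
elements — and suggests juxtapositions ranked by recoverable time.

## Worked example

Two bundled example systems (`ehrfrag.examples`) model a dense and a lean
navigation structure for the same review task, scored with the shortest
routing policy:

```python
from ehrfrag.examples import worked_example_breakdowns

dense, lean, cmp = worked_example_breakdowns()
print(dense.summary_line())
print(lean.summary_line())
print(f"{cmp.ratio:.3f}")
```

prints

```
DFI = 36 + 136 + 136 + 0 + 39 = 347
DFI = 19 + 47 + 47 + 0 + 19 = 132
0.380
```

The dense system needs 36 element accesses, 136 level-weighted screen
transitions and clicks each, and a total menu-length burden of 39 — a DFI
of 347. The leaner structure scores 132, roughly one-third of the dense
system: less navigation for the same clinical content.

On the session side, the demo session (`pogo_example_session`) spends its
140–200 s window alternating between a progress note and lab values three
times each:

```python
from ehrfrag.examples import pogo_example_session
from ehrfrag.task_metrics import task_summary
from ehrfrag.report import detect_pogo_sticking

session = pogo_example_session()
for row in task_summary(session):
    print(row.task_label, row.n_instances, row.act_s, round(row.ppi, 4))
print(detect_pogo_sticking(session, min_repeats=3))
```

shows `Progress Note` and `Lab Values` each split into 3 instances of 10 s
(ACT 10 s, PPI 0.0435 — heavily fragmented), and one pogo finding for the
pair `('note', 'labs')` with counts (3, 3) covering 60 s — juxtaposing the
two elements would remove that navigation entirely.

The same analyses run from the shell:

```sh
ehrfrag simulate tree --depth 3 --branching 3 --n-targets 4 --seed 1 --out tree.csv
ehrfrag nav dfi tree.csv
ehrfrag nav sunburst tree.csv --out sunburst.svg --highlight-targets
ehrfrag simulate session --p-switch 0.5 --seed 1 --out log.csv
ehrfrag log metrics log.csv
ehrfrag report --nav tree.csv --log log.csv --out-dir report/
```

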