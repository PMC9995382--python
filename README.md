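# interviewsim

A training simulator for investigative interviewing of children. Poorly
asked questions — suggestive, closed, repeated — are a leading cause of
unreliable child-witness reports; interviewers improve only with
practice and feedback, which real child interviews cannot ethically
provide. `interviewsim` supplies that practice loop in software:

* A **question-type classifier** codes each interviewer question into an
  11-type taxonomy (5 *recommended* types: broad/focused invitations,
  facilitators, directives, clarifications; 6 *not recommended*:
  option-posing, specific/unspecific suggestive, repetition,
  developmentally inappropriate, multiple-choice). It combines character
  N-gram features (N = 1–5) with an XGBoost softmax tree ensemble,
  wrapped in a deterministic rule layer: greeting if-then rules, Jaccard
  repetition detection against the immediately preceding question, a
  suggestive-keyword override, and topic tagging.
* A **probabilistic child avatar** answers each question from a scripted
  memory of nine relevant details (the last four jointly conclusive
  about whether abuse occurred). A recommended question elicits a
  relevant detail with probability *p* = 0.20 (age-4 avatars) or 0.25
  (age-6), a neutral detail with the same probability, otherwise a
  filler; a not-recommended question creates an *incorrect* detail
  (contradicting the script) with configurable probability; repeating a
  question can flip a previous answer to "Yes".
* **Interventions and evaluation**: automated feedback (case outcome
  plus comments on 2 recommended + 2 not-recommended questions sampled
  from the transcript), a modeling package (learning points + four
  good/bad × abused/non-abused exemplar interviews), percent agreement
  and Cohen's κ with 95% CI, and batch correlations between questioning
  style and elicited details.
* A **synthetic corpus generator** produces labeled question corpora
  (templates with shared slot lexicons, geometric class imbalance,
  adjacent repetition pairs) so the whole system trains and tests
  without any external data.

The package is used from Python; `examples/` contains one short script
per capability. A thin `interviewsim` command-line tool covers the
shell-friendly workflows (corpus generation, training, interactive
interviews, feedback, agreement).

## Worked example

`python examples/03_interview_and_feedback.py` trains a small
classifier, runs a scripted interview against a 4-year-old abused
avatar, and prints each coded turn:

```
[greeting              ] Hello
                         child: Okay.  (none)
[invitation_broad      ] Tell me everything that happened from the beginning to the end
                         child: Maybe.  (none)
[specific_suggestive   ] Did your dad hurt you?
                         child: Hmm...  (none)
[repetition            ] Did your dad hurt you?
                         child: Yes.  (incorrect)
...
outcome measures: {'n_recommended': 4, 'n_not_recommended': 3,
 'prop_recommended': 57.14..., 'n_relevant': 0, 'n_incorrect': 1}
```

The greeting is handled by an if-then rule and excluded from the
counts. Re-asking the suggestive question was coded `repetition`, and
the avatar flipped its non-answer to "Yes." — an incorrect detail,
because it contradicts the avatar's script. The five outcome measures
(recommended/not-recommended counts, percent recommended, relevant and
incorrect detail counts) are the simulator's quality read-out of an
interview.

`python examples/04_batch_simulation.py` runs 100 interviews with
interviewers of varying quality and prints the correlation table; more
recommended questions means more relevant details (r ≈ +0.72) and more
not-recommended questions means more incorrect details (r ≈ +0.71) —
the engine's designed reward structure.

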