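# Narrative text registry (English).  The interpretation sentence is a pure
# function of (scale family, comparator, traffic-light color).  Replace this
# file to localize the feedback.
document:
  title: "Your questionnaire feedback"
  intro: >-
    The charts below show your scores. The colored parts follow a traffic
    light model: yellow means your score is about average, green means better
    than average, and red means worse than average. The dotted purple line
    marks your own score.
  your_score: "Your score:"
comparator_names:
  lymphoma_cohort: "other people with lymphoma of your age and sex"
  normative_population: "people from the general population of your age and sex"
  absolute: "the published severity cutoffs"
interpretation:
  higher_is_better:
    green: >-
      Your score falls in the green part. This indicates that your score is
      higher than the average score of {comparator}.
    amber: >-
      Your score falls in the yellow part. This indicates that your score is
      similar to that of {comparator}.
    red: >-
      Your score falls in the red part. This indicates that your score is
      lower than the average score of {comparator}.
  higher_is_worse:
    green: >-
      Your score falls in the green part. This indicates that you report
      fewer of these symptoms than {comparator}.
    amber: >-
      Your score falls in the yellow part. This indicates that you report
      about as many of these symptoms as {comparator}.
    red: >-
      Your score falls in the red part. This indicates that you report more
      of these symptoms than {comparator}.
  hads:
    green: >-
      Your score falls in the green part (0-7). This indicates no or mild
      symptoms.
    amber: >-
      Your score falls in the yellow part (8-10). This indicates moderate
      symptoms.
    red: >-
      Your score falls in the red part (11 or higher). This indicates severe
      symptoms.
messages:
  unavailable: >-
    A comparison with {comparator} is not available for this topic; the chart
    shows your own score only.
  not_computable: >-
    Too many questions for this topic were left unanswered, so no score
    could be calculated.
  gp_advice: >-
    Your score falls in the red part of the chart. We advise you to discuss
    these symptoms with your general practitioner.
scales:
  general_qol:
    name: "Overall quality of life"
    description: >-
      Overall quality of life summarises how you rate your health and your
      life as a whole. You can score between 0 and 100; the higher the score,
      the better you experience your quality of life.
    context: >-
      Quality of life covers many areas of daily life and can change over
      time, for example during and after treatment.
  physical:
    name: "Physical functioning"
    description: >-
      Physical functioning refers to activities such as walking, climbing
      stairs and carrying things. You can score between 0 and 100; the higher
      the score, the better your physical functioning.
    context: >-
      Physical fitness is often reduced during treatment and usually recovers
      gradually afterwards.
  emotional:
    name: "Emotional functioning"
    description: >-
      Emotional functioning refers to feelings such as tension, worry,
      irritability and depressed mood. You can score between 0 and 100; the
      higher the score, the better your emotional well-being.
    context: >-
      Feelings of worry or sadness are common among people who have or have
      had cancer, and they often lessen with time.
  cognitive:
    name: "Cognitive functioning"
    description: >-
      Cognitive functioning is a component of quality of life. It refers, for
      example, to the extent to which you can concentrate or remember things.
      You can score between 0 and 100; the higher the score, and the closer
      it is to 100, the higher you will experience your quality of life in
      this part.
    context: >-
      People with lymphoma generally score lower on cognitive functioning
      than the general population. Memory and concentration problems are
      common among people with cancer. Some also experience difficulty
      working under time pressure or doing different things at the same time;
      others must make a greater mental effort to reach the same results as
      before the illness.
  social:
    name: "Social functioning"
    description: >-
      Social functioning refers to the extent to which your physical
      condition or treatment interferes with family life and social
      activities. You can score between 0 and 100; the higher the score, the
      better your social functioning.
    context: >-
      Illness and treatment can make it harder to take part in family and
      social life; for many people this improves after treatment ends.
  fatigue:
    name: "Fatigue"
    description: >-
      This score reflects how tired, weak or in need of rest you have felt.
      You can score between 0 and 100; the higher the score, the more fatigue
      you report.
    context: >-
      Fatigue is one of the most frequently reported symptoms during and
      after cancer treatment. Balancing activity and rest can help; persistent
      severe fatigue is worth discussing with a professional.
  tingling:
    name: "Tingling hands or feet"
    description: >-
      This score reflects tingling in your hands or feet, a symptom of nerve
      irritation that can occur after some treatments. You can score between
      0 and 100; the higher the score, the more tingling you report.
    context: >-
      Tingling hands or feet are relatively common among people treated for
      lymphoma; the symptom can diminish slowly over months.
  anxiety:
    name: "Anxiety"
    description: >-
      This score reflects feelings of tension, worry and fear over the past
      week. You can score between 0 and 21; the higher the score, the more
      anxiety symptoms you report.
    context: >-
      Some anxiety is a normal reaction to illness. Scores of 11 or higher
      indicate symptoms severe enough to merit professional attention.
  depressive:
    name: "Depressive symptoms"
    description: >-
      This score reflects loss of interest and enjoyment and low mood over
      the past week. You can score between 0 and 21; the higher the score,
      the more depressive symptoms you report.
    context: >-
      Low mood is common during and after cancer treatment. Scores of 11 or
      higher indicate symptoms severe enough to merit professional attention.
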