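# 42-year-old referred for unexpected poor responses to psychotropics and pain killers.
patient:
  age: 42
  sex: male
  referral_reason: "poor responses to psychotropics and pain killers"
medications:
  - name: codeine
    status: past
    dose_text: "30 mg up to qid"
    duration_text: "6 weeks"
    trial_adequate: yes
    outcome: poor_efficacy
  - name: clomipramine
    status: current
    dose_text: "150 mg daily"
    duration_text: "3 months"
    trial_adequate: yes
    outcome: poor_efficacy
comedications: []
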