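# Performance shaping factor taxonomy for medication-error assessment:
# 17 subPSFs in 3 categories, with the fuzzy-AHP weights from the published
# emergency-department study.  Definitions are abridged.
categories:
  - name: personal
    subpsfs:
      - label: Knowledge
        definition: Information and understanding of the subject that the person holds.
        weight: 0.237
      - label: Experience
        definition: Work-related knowledge accumulated over the years.
        weight: 0.270
      - label: Fatigue
        definition: Lack of energy and of the mental drive needed to continue a job.
        weight: 0.313
      - label: Physical health
        definition: Freedom of the body from disease or abnormal conditions.
        weight: 0.065
      - label: Task time (circadian rhythm)
        definition: Time of day at which the task is carried out.
        weight: 0.114
  - name: job
    subpsfs:
      - label: Workload
        definition: Relation between mental processing capacity and the amount of work demanded.
        weight: 0.385
      - label: Availability of work procedures
        definition: Specification of who does what, when, and under which criteria.
        weight: 0.175
      - label: Physical environment
        definition: Ambient conditions such as weather, ward environment, nursing station and medication store conditions.
        weight: 0.039
      - label: Housekeeping
        definition: Crowding, noise, telephone interruptions, space constraints and bystanders in the work area.
        weight: 0.135
      - label: Transparency of responsibilities
        definition: How clearly each person's task is assigned to that person.
        weight: 0.110
      - label: Time available
        definition: Time frame within which staff must act in an abnormal event.
        weight: 0.156
  - name: organization
    subpsfs:
      - label: Patient safety climate
        definition: Shared understanding of which patient-safety practices and behaviours are rewarded and supported.
        weight: 0.225
      - label: Safety culture
        definition: Beliefs, values, attitudes and behaviour patterns determining the organization's commitment to safe care.
        weight: 0.209
      - label: Training
        definition: Systematic development of the knowledge, skills and attitudes a task requires.
        weight: 0.210
      - label: Communication between staff
        definition: Transfer of information and understanding from one person to another.
        weight: 0.099
      - label: Supervising staff
        definition: Planning, organizing, directing and controlling of work and employee activities.
        weight: 0.120
      - label: Error management culture
        definition: Communicating and dealing with errors and their consequences after they occur.
        weight: 0.136
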