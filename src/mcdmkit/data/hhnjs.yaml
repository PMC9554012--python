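# Home Healthcare Nurse Job Satisfaction Scale (HHNJS): 30 items in 8
# dimensions, each rated on a 5-point Likert scale.  Item order defines the
# pairwise-comparison chains used for weight elicitation.
name: HHNJS
dimensions:
  - id: C1
    label: Relationship with patients
    criteria:
      - {id: C11, label: "Patients are satisfied with the care that I provide"}
      - {id: C12, label: "The relationships that I have established with patients are rewarding"}
      - {id: C13, label: "I have helped patients maintain or improve their quality of life"}
      - {id: C14, label: "My work is important and worthwhile"}
      - {id: C15, label: "The patient care that I provide adheres to my professional standards"}
  - id: C2
    label: Relationship with peer
    criteria:
      - {id: C21, label: "The support I have from my nursing peers is a positive aspect of my job"}
      - {id: C22, label: "I can communicate comfortably with the nurses I work with"}
      - {id: C23, label: "There is a good amount of collegiality among the nurses I work with"}
      - {id: C24, label: "I have peers whom I can rely on and turn to if necessary"}
  - id: C3
    label: Professional pride
    criteria:
      - {id: C31, label: "If I had to do it over again, I would choose home healthcare as my area of practice"}
      - {id: C32, label: "I would commend my job to another health care professional"}
      - {id: C33, label: "I am proud to talk to people about the work I do"}
  - id: C4
    label: Salary and benefit
    criteria:
      - {id: C41, label: "My present salary is satisfactory"}
      - {id: C42, label: "An upgrading of the pay scales at this agency is needed", reverse_worded: true}
      - {id: C43, label: "Nursing salaries at other agencies are better than salaries at this agency", reverse_worded: true}
      - {id: C44, label: "The benefit package at this agency is satisfactory to me"}
  - id: C5
    label: Relationship with physician
    criteria:
      - {id: C51, label: "Physicians value my input on the status of their home healthcare patients"}
      - {id: C52, label: "I am treated as a professional colleague by physicians"}
  - id: C6
    label: Relationship with organization
    criteria:
      - {id: C61, label: "I am satisfied with the professional relationship that I have with nursing administration at this agency"}
      - {id: C62, label: "I have the power to generate change in organizational policy at this agency"}
      - {id: C63, label: "I have the opportunity to grow and develop as a professional nurse within this agency"}
  - id: C7
    label: Autonomy and control
    criteria:
      - {id: C71, label: "I am able to adjust the hours of my work if needed"}
      - {id: C72, label: "I have more flexibility in my hours of work than nurses in other practice settings"}
      - {id: C73, label: "I have sufficient control over scheduling my time"}
      - {id: C74, label: "I have the independence to make important decisions in my day-to-day work"}
  - id: C8
    label: Stress and workload
    criteria:
      - {id: C81, label: "At times I am overwhelmed by all the work I have to do", reverse_worded: true}
      - {id: C82, label: "I could deliver better patient care if I had more time", reverse_worded: true}
      - {id: C83, label: "I am able to meet the demands of my job"}
      - {id: C84, label: "I am able to cope with the increased demands for documentation in home care"}
      - {id: C85, label: "Sometimes I get frustrated because all my activities are programmed for me", reverse_worded: true}
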