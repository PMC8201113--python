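# Default hospital service-quality instrument: 4 dimensions, 31 attributes,
# each carrying one functional and one dysfunctional five-point item.
name: hospital-service-quality
dimensions:
  - name: health_personnel
    attributes:
      - {id: 1, text: "Level of professionalism"}
      - {id: 2, text: "Kindness and courtesy of health personnel"}
      - {id: 3, text: "Confidence in health personnel"}
      - {id: 4, text: "Personalized service"}
      - {id: 5, text: "Communication"}
      - {id: 6, text: "Individualized care provided by healthcare personnel"}
      - {id: 7, text: "Interest in attending to the patient's problem"}
      - {id: 8, text: "Interest in understanding the problems of the patient"}
      - {id: 9, text: "Prestige of healthcare personnel"}
      - {id: 10, text: "Detailed explanation of the diagnosis and treatment"}
  - name: non_health_personnel
    attributes:
      - {id: 11, text: "Level of professionalism"}
      - {id: 12, text: "Kindness and courtesy"}
      - {id: 13, text: "Individualized care toward the problems of the patient"}
      - {id: 14, text: "Interest in attending to the patient's problems"}
  - name: facilities_equipment_tangibles
    attributes:
      - {id: 15, text: "Cleanliness"}
      - {id: 16, text: "Equipment"}
      - {id: 17, text: "Accessibility"}
      - {id: 18, text: "Appearance and presence of healthcare personnel"}
      - {id: 19, text: "Appearance and presence of non-healthcare personnel"}
      - {id: 20, text: "Clear signage for each department in the hospital"}
  - name: efficiency
    attributes:
      - {id: 21, text: "Arranging a medical appointment"}
      - {id: 22, text: "Level of bureaucracy"}
      - {id: 23, text: "Waiting time in the healthcare center"}
      - {id: 24, text: "Computerized service"}
      - {id: 25, text: "Ancillary testing"}
      - {id: 26, text: "Resolution of complaints"}
      - {id: 27, text: "Time spent on the care of patients"}
      - {id: 28, text: "Hours of the healthcare center"}
      - {id: 29, text: "Medical expense"}
      - {id: 30, text: "Improvement in the medical condition"}
      - {id: 31, text: "Side effects when taking medicines"}
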