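review_id,title,n_included,n_retrievable,s1_full_sens,s4_full_sens,s1_full_ppv,s4_full_ppv,s1_2p_sens,s4_2p_sens,s1_2p_ppv,s4_2p_ppv
1,Carbamazepine versus phenytoin monotherapy for epilepsy,10,8,37.5,37.5,0.1,11.1,0.0,37.5,0.0,11.1
2,Chest physiotherapy for pneumonia in adults,6,5,100.0,80.0,1.9,12.5,0.0,80.0,0.0,12.5
3,Epinephrine injection versus epinephrine injection and a second endoscopic method in high risk bleeding ulcers,18,15,100.0,100.0,7.9,19.5,6.7,33.3,2.5,12.5
4,Extracranial-intracranial arterial bypass surgery for occlusive carotid artery disease,21,18,38.9,5.6,4.1,14.3,0.0,5.6,0.0,14.3
5,Fluticasone versus extrafine HFA-beclomethasone dipropionate for chronic asthma in adults and children,9,8,100.0,100.0,18.6,42.1,100.0,100.0,20.0,42.1
6,Influenza vaccination for healthcare workers who work with the elderly,5,5,100.0,80.0,1.5,16.7,20.0,80.0,2.5,16.7
7,Mucolytic agents for chronic bronchitis or chronic obstructive pulmonary disease,29,18,83.3,66.7,11.5,18.8,22.2,38.9,10.0,17.5
8,Neuraminidase inhibitors for preventing and treating influenza in healthy adults,20,20,90.0,90.0,22.8,35.3,15.0,70.0,7.5,35.0
9,Adenoidectomy for otitis media in children,14,14,100.0,100.0,2.3,22.2,7.1,64.3,2.5,22.5
10,Antibiotics and antiseptics for venous leg ulcers,25,13,84.6,76.9,6.4,43.5,15.4,76.9,5.0,43.5
11,Antithyroid drug regimen for treating Graves hyperthyroidism,27,23,82.6,78.3,4.9,36.7,0.0,69.6,0.0,40.0
12,Artesunate versus quinine for treating severe malaria,6,4,100.0,100.0,8.3,33.3,50.0,100.0,5.0,33.3
13,Bed rest for acute uncomplicated myocardial infarction,17,11,54.5,27.3,19.4,60.0,54.5,27.3,19.4,60.0
14,Benzodiazepines for the relief of breathlessness in advanced malignant and non-malignant diseases in adults,7,4,75.0,50.0,10.7,40.0,75.0,50.0,10.7,40.0
15,Blood pressure lowering efficacy of beta-blockers as second-line therapy for primary hypertension,20,11,72.7,63.6,1.2,2.3,0.0,0.0,0.0,0.0
16,Blood pressure lowering efficacy of potassium-sparing diuretics for primary hypertension,8,7,100.0,71.4,1.2,2.5,0.0,0.0,0.0,0.0
17,Caffeine for asthma,7,7,85.7,71.4,66.7,83.3,85.7,71.4,66.7,83.3
18,Continuous subcutaneous insulin infusion (CSII) versus multiple insulin injections for type 1 diabetes mellitus,34,27,66.7,55.6,9.9,44.1,7.4,55.6,5.0,44.1
19,Effect of cyclosporine on blood pressure,17,17,47.1,47.1,9.3,11.9,17.6,23.5,7.5,10.0
20,Enteral versus parenteral nutrition for acute pancreatitis,8,8,100.0,100.0,3.9,30.8,12.5,100.0,2.5,30.8
21,Exercises for prevention of recurrences of low-back pain,13,13,84.6,84.6,0.5,2.7,0.0,0.0,0.0,0.0
22,Home-based versus centre-based cardiac rehabilitation,22,17,58.8,47.1,7.8,15.4,29.4,47.1,12.5,20.0
23,Immediate-release versus controlled-release carbamazepine in the treatment of epilepsy,10,10,80.0,80.0,11.8,34.8,30.0,80.0,7.5,34.8
24,Proton pump inhibitor treatment initiated prior to endoscopic diagnosis in upper gastrointestinal bleeding,6,3,33.3,33.3,0.9,14.3,0.0,33.3,0.0,14.3
25,Rectal 5-aminosalicylic acid for induction of remission in ulcerative colitis,38,33,90.9,84.8,10.3,32.6,12.1,39.4,10.0,32.5
26,Regular treatment with salmeterol for chronic asthma: serious adverse events,49,30,43.3,40.0,7.6,18.8,0.0,16.7,0.0,12.5
27,Rifabutin for treating pulmonary tuberculosis,5,4,100.0,100.0,2.7,33.3,0.0,100.0,0.0,33.3
28,Serotonin receptor antagonists for highly emetogenic chemotherapy in adults,16,15,46.7,46.7,2.2,7.3,6.7,13.3,2.5,5.0
29,Short-term treatment with proton pump inhibitors and H2-receptor antagonists and prokinetics for gastro-oesophageal reflux disease-like symptoms and endoscopy negative reflux disease,45,38,57.9,55.3,0.7,4.4,0.0,0.0,0.0,0.0
30,Therapeutic ultrasound for osteoarthritis of the knee or hip,5,5,100.0,100.0,9.4,29.4,100.0,100.0,12.5,29.4
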