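task_id,task_title,subtask_id,description
1,Admitting patient and recording information,1.1,Recording patient demographic information on all pages of the patient records file (PRF)
1,Admitting patient and recording information,1.2,Registration of patient bed number in the PRF
1,Admitting patient and recording information,1.3,Writing the patient's medical history in the PRF
1,Admitting patient and recording information,1.4,Placing the identification wristband on the patient's wrist
2,Examination and registration of required medications,2.1,Initial examination of the patient by physician and nurse and recording the detailed medication process
2,Examination and registration of required medications,2.2,Striking through medications no longer prescribed with a red pen and writing D.C. in front of them
2,Examination and registration of required medications,2.3,Recording information about new medications in the PRF
2,Examination and registration of required medications,2.4,Writing medication information (name dosage prescription and time) in the patient's Kardex based on the PRF
2,Examination and registration of required medications,2.5,Clearing out old medicines from the patient card
2,Examination and registration of required medications,2.6,Writing medication information in the patient's card based on the PRF using a pencil
2,Examination and registration of required medications,2.7,Registration of the required medications in the hospital information system
3,Receiving and storing medications,3.1,Receiving the prescribed medications from the hospital drugstore by an assistant
3,Receiving and storing medications,3.2,Receiving medications from the assistant by a nurse
3,Receiving and storing medications,3.3,Initial review of medications by the nurse for detection of any discrepancy
3,Receiving and storing medications,3.4,Separating sensitive medications (requiring non-routine prescribing instructions) from non-sensitive ones
3,Receiving and storing medications,3.5,Labeling sensitive medications with the prescription protocol
3,Receiving and storing medications,3.6,Separating refrigerated medications from non-refrigerated ones
3,Receiving and storing medications,3.7,Putting the medications in the medication room on the designated shelves
4,Preparation of medications,4.1,Finding the patient's medication card
4,Preparation of medications,4.2,Reading medication information from the medication card
4,Preparation of medications,4.3,Finding medications in the medication room
4,Preparation of medications,4.4,Picking medications from the designated shelves
4,Preparation of medications,4.5,Checking medication name prescription instructions and expiry date
4,Preparation of medications,4.6,Obtaining the desired dosage of the medication and preparing it if required
4,Preparation of medications,4.7,Transferring the prepared medications to the emergency ward in special trays
5,Prescribing medication to the patient,5.1,Identifying the intended patient in the emergency ward
5,Prescribing medication to the patient,5.2,Asking the patient their name
5,Prescribing medication to the patient,5.3,Matching the patient name with their wristband
5,Prescribing medication to the patient,5.4,Checking the prescription guidelines and determining the administration route
5,Prescribing medication to the patient,5.5,Prescribing medications under their instructions
5,Prescribing medication to the patient,5.6,Checking the patient for probable side effects for up to 15 minutes
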